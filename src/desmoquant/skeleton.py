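"""Keratin network density from skeletonized filament images.

The filament image is thresholded (same parameters across all groups of one
analysis run), thinned to unit-width centerlines, and converted to a graph
whose edges are filament bundles and whose nodes are bundle junctions
(skeleton pixels with >= 3 skeleton neighbors, with adjacent junction
pixels merged into a single node) or end points.  Network density is then
the number of bundles, respectively bundle junctions, per ROI area in µm².

8-connectivity is used throughout.  Short end-point spurs produced by noise
can be pruned before counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _thin

from .core import DesmoquantError, ThresholdError, as_pixels

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class BinaryImage:
    """A thresholded foreground mask with the threshold recorded."""

    mask: np.ndarray
    threshold: float | None = None
    method: str = "fixed"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def binarize(image, method: str = "otsu", threshold: float | None = None) -> BinaryImage:
    """Threshold a filament image to a foreground mask.

    ``method='otsu'`` picks the threshold automatically (foreground = above
    threshold); ``method='fixed'`` uses ``threshold`` (foreground = at or
    above).  The applied threshold is recorded on the result so that the
    same parameters can be re-applied across groups.  A constant image
    cannot be auto-thresholded and raises :class:`ThresholdError`.
    """
    pixels = as_pixels(image)
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold value")
        return BinaryImage(pixels >= threshold, float(threshold), "fixed")
    if method == "otsu":
        if np.ptp(pixels) == 0:
            raise ThresholdError("constant image: automatic thresholding impossible; "
                                 "use method='fixed' with an explicit threshold")
        t = float(threshold_otsu(pixels))
        return BinaryImage(pixels > t, t, "otsu")
    raise ValueError("method must be 'otsu' or 'fixed'")


# --------------------------------------------------------------------------
# skeleton graph extraction
# --------------------------------------------------------------------------

@dataclass
class SkeletonEdge:
    """One branch: an 8-connected run of skeleton pixels between nodes."""

    pixels: np.ndarray           # (L, 2)
    node_ids: tuple              # ids of junction nodes it touches (0-2)
    has_endpoint: bool           # touches a degree-1 skeleton pixel

    @property
    def length_px(self) -> int:
        return len(self.pixels)


@dataclass
class SkeletonGraph:
    """A unit-width skeleton with its branch/junction decomposition.

    Junction nodes are connected clusters of skeleton pixels that have >= 3
    skeleton neighbors; edges are the connected runs of the remaining
    pixels.  Junction pixels, edge pixels (and isolated pixels, which form
    single-pixel edges) partition the skeleton.
    """

    skeleton: np.ndarray                     # bool
    edges: list = field(default_factory=list)
    junction_pixels: dict = field(default_factory=dict)   # node id -> (K, 2)

    @property
    def n_branches(self) -> int:
        return len(self.edges)

    @property
    def n_junctions(self) -> int:
        return len(self.junction_pixels)

    @property
    def n_endpoints(self) -> int:
        return int(np.count_nonzero(_neighbor_counts(self.skeleton) == 1))

    @property
    def n_components(self) -> int:
        _, n = ndimage.label(self.skeleton, structure=_STRUCT8)
        return int(n)

    def coarse_counts(self, min_junction_sep_px: float) -> tuple[int, int]:
        """(n_branches, n_junctions) after merging junctions closer than
        ``min_junction_sep_px`` (measured along the connecting branch).

        Junction pairs separated by less than the imaging resolution are not
        reliably distinguishable; comparing coarse counts at a stated
        separation makes skeleton metrics comparable across pipelines.
        """
        edge_list = []
        for i, e in enumerate(self.edges):
            ids = list(e.node_ids)
            while len(ids) < 2:
                ids.append(f"leaf_{i}_{len(ids)}")
            edge_list.append((ids[0], ids[1], float(e.length_px)))
        return _contract_short_junction_edges(edge_list, min_junction_sep_px)


def _contract_short_junction_edges(edge_list, tol: float) -> tuple[int, int]:
    """Coarsen a branch graph to a stated spatial resolution.

    Iteratively (a) contracts edges shorter than ``tol`` joining two branch
    points (degree >= 3) — junction pairs closer than the resolution — and
    (b) drops terminal (degree-1) edges shorter than ``tol`` — stubs below
    the resolution.  ``edge_list`` holds (u, v, length) triples; returns the
    remaining (edge count, junction count)."""
    import networkx as nx

    g = nx.MultiGraph()
    for u, v, length in edge_list:
        g.add_edge(u, v, length=length)
    changed = True
    while changed:
        changed = False
        for u, v, k, d in list(g.edges(keys=True, data=True)):
            if d["length"] >= tol or u == v:
                continue
            du, dv = g.degree(u), g.degree(v)
            if du >= 3 and dv >= 3:
                g = nx.contracted_nodes(g, u, v, self_loops=False)
                changed = True
                break
            if du == 1 or dv == 1:
                g.remove_edge(u, v, key=k)
                g.remove_nodes_from([n for n in (u, v) if g.degree(n) == 0])
                changed = True
                break
    n_junctions = sum(1 for _, deg in g.degree() if deg >= 3)
    return g.number_of_edges(), n_junctions


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    counts = ndimage.convolve(skel.astype(np.uint8), _STRUCT8.astype(np.uint8),
                              mode="constant", cval=0)
    return np.where(skel, counts - 1, 0)


def _extract_graph(skel: np.ndarray) -> SkeletonGraph:
    skel = np.asarray(skel, dtype=bool)
    nc = _neighbor_counts(skel)
    junction_px = skel & (nc >= 3)
    jlab, n_nodes = ndimage.label(junction_px, structure=_STRUCT8)
    junction_pixels = {i: np.argwhere(jlab == i) for i in range(1, n_nodes + 1)}

    branch_px = skel & ~junction_px
    blab, n_branch = ndimage.label(branch_px, structure=_STRUCT8)
    end_px = skel & (nc == 1)
    edges = []
    for k in range(1, n_branch + 1):
        comp = blab == k
        pix = np.argwhere(comp)
        # junction nodes adjacent to this branch
        dil = ndimage.binary_dilation(comp, structure=_STRUCT8)
        touching = np.unique(jlab[dil & junction_px])
        touching = tuple(int(t) for t in touching if t != 0)
        isolated = len(pix) == 1 and nc[pix[0, 0], pix[0, 1]] == 0
        edges.append(SkeletonEdge(pixels=pix, node_ids=touching,
                                  has_endpoint=bool(end_px[comp].any() or isolated)))
    return SkeletonGraph(skeleton=skel, edges=edges, junction_pixels=junction_pixels)


def skeletonize(mask) -> SkeletonGraph:
    """Thin a foreground mask to unit width and extract its branch graph.

    Uses two-subiteration morphological thinning; the result contains no
    2x2 all-foreground block and is 8-connected.  An empty mask yields an
    empty graph.
    """
    m = mask.mask if isinstance(mask, BinaryImage) else np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not m.any():
        return SkeletonGraph(skeleton=np.zeros_like(m))
    return _extract_graph(_thin(m))


def prune_spurs(graph: SkeletonGraph, min_branch_px: int) -> SkeletonGraph:
    """Iteratively remove end-point branches shorter than ``min_branch_px``.

    After each removal pass the remaining pixels are re-thinned and the
    graph re-extracted, so junctions whose spur disappeared dissolve into
    through-paths.  Pruning is idempotent; ``min_branch_px = 0`` returns
    the graph unchanged.
    """
    if min_branch_px < 0:
        raise ValueError("min_branch_px must be >= 0")
    if min_branch_px == 0:
        return graph
    current = graph
    for _ in range(100):
        spurs = [e for e in current.edges
                 if e.has_endpoint and e.length_px < min_branch_px]
        if not spurs:
            return current
        skel = current.skeleton.copy()
        for e in spurs:
            skel[e.pixels[:, 0], e.pixels[:, 1]] = False
        if not skel.any():
            return SkeletonGraph(skeleton=skel)
        current = _extract_graph(_thin(skel))
    return current


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass
class SkeletonMetrics:
    roi_area_um2: float
    n_bundles: int
    n_junctions: int
    n_components: int
    bundle_density: float      # per µm²
    junction_density: float    # per µm²


def _roi_mask(roi, shape) -> np.ndarray:
    arr = np.asarray(roi)
    if arr.dtype == bool:
        if arr.shape != shape:
            raise ValueError("ROI mask shape must match the image")
        return arr
    r0, c0, r1, c1 = (int(v) for v in arr.ravel())
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ValueError("ROI rectangle (r0, c0, r1, c1) out of image bounds")
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


def skeleton_metrics(graph: SkeletonGraph, roi, pixel_size_um: float) -> SkeletonMetrics:
    """Bundle and junction densities of a skeleton graph inside an ROI.

    ``roi`` is either a boolean mask or a (r0, c0, r1, c1) rectangle.  A
    branch (or junction node) is counted when at least 50% of its pixels
    fall inside the ROI.  Area is the ROI pixel count times the squared
    pixel size.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    mask = _roi_mask(roi, graph.skeleton.shape)
    area_px = int(mask.sum())
    if area_px == 0:
        raise DesmoquantError("ROI has zero area")
    area_um2 = area_px * pixel_size_um ** 2

    def _inside_frac(pix: np.ndarray) -> float:
        return float(mask[pix[:, 0], pix[:, 1]].mean()) if len(pix) else 0.0

    n_bundles = sum(1 for e in graph.edges if _inside_frac(e.pixels) >= 0.5)
    n_junctions = sum(1 for pix in graph.junction_pixels.values()
                      if _inside_frac(pix) >= 0.5)
    # connected components restricted to the ROI, reported for transparency
    _, n_comp = ndimage.label(graph.skeleton & mask, structure=_STRUCT8)
    return SkeletonMetrics(
        roi_area_um2=float(area_um2),
        n_bundles=n_bundles,
        n_junctions=n_junctions,
        n_components=int(n_comp),
        bundle_density=n_bundles / area_um2,
        junction_density=n_junctions / area_um2,
    )
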