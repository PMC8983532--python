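"""Line-scan quantification of junctional protein enrichment.

Short intensity profiles ("line scans") are placed perpendicular to traced
bicellular borders.  Each profile is split into a junctional band centred on
the border crossing and cytoplasmic bands at its ends; the ratio of the mean
junctional to the mean cytoplasmic intensity quantifies enrichment of the
stained protein at the cell-cell contact.  Profiles can additionally be
normalized to the cytoplasmic mean to overlay average distributions.

No background subtraction is performed; the ratio is invariant under a global
multiplicative rescaling of the image, so camera gain and exposure cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import DesmoquantError, IntensityImage, as_labels, as_pixels


# --------------------------------------------------------------------------
# border tracing
# --------------------------------------------------------------------------

@dataclass
class BorderTrace:
    """An ordered 8-connected pixel path along one bicellular interface.

    ``pixels`` are (row, col) coordinates of the trace, taken on the side of
    the lower-numbered cell of ``label_pair``.  The source label mask is kept
    so segment placement can reject scans that stray into a third cell.
    """

    label_pair: tuple[int, int]
    pixels: np.ndarray  # (N, 2) int
    labels: np.ndarray | None = None  # source label mask (reference)

    def __len__(self) -> int:
        return len(self.pixels)


_NEIGH = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def _order_path(coords: np.ndarray) -> np.ndarray:
    """Order a thin 8-connected pixel set into a path by greedy chaining.

    Starts from a pixel with the fewest neighbors (an end of the path; for
    closed loops the start is arbitrary) and repeatedly steps to the nearest
    unvisited neighbor, preferring 4-adjacency over diagonal moves.
    """
    pts = [tuple(p) for p in coords]
    pset = set(pts)

    def neighbors(p):
        return [(p[0] + dr, p[1] + dc) for dr, dc in _NEIGH if (p[0] + dr, p[1] + dc) in pset]

    start = min(pts, key=lambda p: (len(neighbors(p)), p))
    path = [start]
    visited = {start}
    current = start
    while True:
        cands = [q for q in neighbors(current) if q not in visited]
        if not cands:
            # jump to any remaining pixel adjacent to the path (thin forks)
            rest = pset - visited
            cands = [q for q in rest if any(abs(q[0] - p[0]) <= 1 and abs(q[1] - p[1]) <= 1 for p in path[-3:])]
            if not cands:
                break
        # prefer 4-adjacent continuation, then lexicographic for determinism
        cands.sort(key=lambda q: (abs(q[0] - current[0]) + abs(q[1] - current[1]), q))
        current = cands[0]
        path.append(current)
        visited.add(current)
    # leftover pixels (rare side branches of a thick interface) are dropped
    return np.array(path, dtype=int)


def trace_borders(mask) -> list[BorderTrace]:
    """Trace every bicellular interface of a cell label mask.

    Returns one ordered trace per connected interface between a pair of
    adjacent cell labels.  Pixels whose 8-neighborhood contains three or more
    distinct cell labels (tricellular corners) are excluded from all traces.
    A mask with no adjacent label pair yields an empty list.
    """
    labels = as_labels(mask)
    labs = np.unique(labels)
    labs = labs[labs > 0]
    if len(labs) < 2:
        return []

    struct = np.ones((3, 3), dtype=bool)
    # per-label window indicator: True where the 3x3 window contains label l
    indicators = {int(l): ndimage.binary_dilation(labels == l, structure=struct) for l in labs}
    n_in_window = np.sum([ind for ind in indicators.values()], axis=0)
    tricellular = n_in_window >= 3

    traces: list[BorderTrace] = []
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            a, b = int(a), int(b)
            pair_mask = (labels == a) & indicators[b] & ~tricellular
            if not pair_mask.any():
                continue
            comp, n_comp = ndimage.label(pair_mask, structure=struct)
            for k in range(1, n_comp + 1):
                coords = np.argwhere(comp == k)
                traces.append(BorderTrace((a, b), _order_path(coords), labels))
    return traces


# --------------------------------------------------------------------------
# segment placement
# --------------------------------------------------------------------------

@dataclass
class LineScanSegment:
    """An oriented sampling window crossing a border.

    The profile runs along ``direction`` (the local border normal) through
    ``center``; intensities are averaged across ``width_px`` parallel samples
    offset along the local tangent.  ``junctional_band`` and
    ``cytoplasmic_band`` are index arrays into the profile and are disjoint.
    """

    center: np.ndarray          # (row, col), float
    direction: np.ndarray       # unit normal, (drow, dcol)
    tangent: np.ndarray         # unit tangent, (drow, dcol)
    length_px: int
    width_px: int
    junctional_band: np.ndarray
    cytoplasmic_band: np.ndarray


def _local_frame(path: np.ndarray, i: int, halfwin: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Unit tangent/normal at path index i from a centered window."""
    h = min(halfwin, i, len(path) - 1 - i)
    h = max(h, 1)
    t = path[min(i + h, len(path) - 1)] - path[max(i - h, 0)]
    t = np.asarray(t, dtype=float)
    n = np.linalg.norm(t)
    if n == 0:
        raise DesmoquantError("cannot estimate border direction from a single pixel")
    t /= n
    normal = np.array([t[1], -t[0]])
    return t, normal


def _band_indices(length_px: int, junction_band_px: int, cyto_fraction: float):
    c0 = (length_px - 1) // 2
    half = max(0, junction_band_px // 2)
    junc = np.arange(c0 - half, c0 + half + 1)
    n_cyto = max(1, int(round(cyto_fraction * length_px)))
    cyto = np.concatenate([np.arange(0, n_cyto), np.arange(length_px - n_cyto, length_px)])
    if junc[0] <= cyto[n_cyto - 1] or junc[-1] >= cyto[n_cyto]:
        raise ValueError(
            "junctional and cytoplasmic bands overlap; increase length_px or "
            "decrease junction_band_px/cyto_fraction"
        )
    return junc, cyto


def place_line_scans(
    trace: BorderTrace,
    spacing_px: int,
    length_px: int = 31,
    width_px: int = 3,
    *,
    junction_band_px: int = 3,
    cyto_fraction: float = 0.25,
) -> list[LineScanSegment]:
    """Place line-scan segments along a border trace.

    Segments are centered every ``spacing_px`` pixels along the trace and
    oriented along the local border normal.  Segments that would leave the
    image, or whose samples fall into a cell other than the trace's label
    pair, are dropped.  Placement is deterministic.

    The junctional band covers the central ``junction_band_px`` samples of
    the profile (default 3, i.e. 3x a one-pixel-wide border); the cytoplasmic
    band is the outer ``cyto_fraction`` of samples at each end.
    """
    if length_px < 5 or length_px % 2 == 0:
        raise ValueError("length_px must be odd and >= 5")
    if spacing_px < 1:
        raise ValueError("spacing_px must be >= 1")
    junc, cyto = _band_indices(length_px, junction_band_px, cyto_fraction)

    path = trace.pixels
    labels = trace.labels
    if labels is not None:
        shape = labels.shape
    else:
        shape = None

    segments: list[LineScanSegment] = []
    offsets = np.arange(length_px, dtype=float) - (length_px - 1) / 2.0
    woff = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0
    for i in range(spacing_px // 2, len(path), spacing_px):
        try:
            tangent, normal = _local_frame(path, i)
        except DesmoquantError:
            continue
        center = path[i].astype(float)
        # sample lattice: along normal (profile) x along tangent (width)
        pts = (center[None, None, :]
               + offsets[:, None, None] * normal[None, None, :]
               + woff[None, :, None] * tangent[None, None, :])
        if shape is not None:
            r, c = pts[..., 0], pts[..., 1]
            if r.min() < 0 or c.min() < 0 or r.max() > shape[0] - 1 or c.max() > shape[1] - 1:
                continue
            rr = np.clip(np.rint(r).astype(int), 0, shape[0] - 1)
            cc = np.clip(np.rint(c).astype(int), 0, shape[1] - 1)
            hit = np.unique(labels[rr, cc])
            if not np.all(np.isin(hit, trace.label_pair)):
                continue
        segments.append(LineScanSegment(center, normal, tangent, length_px, width_px,
                                        junc.copy(), cyto.copy()))
    return segments


# --------------------------------------------------------------------------
# measurement
# --------------------------------------------------------------------------

@dataclass
class LineScanResult:
    junctional_mean: float
    cytoplasmic_mean: float
    ratio: float
    profile: np.ndarray
    normalized_profile: np.ndarray


def measure_line_scan(image, segment: LineScanSegment) -> LineScanResult:
    """Sample a segment's profile and compute the junction/cytoplasm ratio.

    The profile is sampled by bilinear interpolation, averaging ``width_px``
    parallel lines.  The ratio is the junctional-band mean divided by the
    cytoplasmic-band mean; the normalized profile divides every sample by the
    cytoplasmic mean so its cytoplasmic level is 1.
    """
    pixels = as_pixels(image)
    L, W = segment.length_px, segment.width_px
    offsets = np.arange(L, dtype=float) - (L - 1) / 2.0
    woff = np.arange(W, dtype=float) - (W - 1) / 2.0
    pts = (segment.center[None, None, :]
           + offsets[:, None, None] * segment.direction[None, None, :]
           + woff[None, :, None] * segment.tangent[None, None, :])
    if (pts[..., 0].min() < 0 or pts[..., 1].min() < 0
            or pts[..., 0].max() > pixels.shape[0] - 1
            or pts[..., 1].max() > pixels.shape[1] - 1):
        raise DesmoquantError("line-scan segment extends outside the image")
    samples = ndimage.map_coordinates(
        pixels, [pts[..., 0].ravel(), pts[..., 1].ravel()], order=1, mode="nearest"
    ).reshape(L, W)
    profile = samples.mean(axis=1)
    junctional_mean = float(profile[segment.junctional_band].mean())
    cytoplasmic_mean = float(profile[segment.cytoplasmic_band].mean())
    if cytoplasmic_mean == 0:
        raise DesmoquantError("cytoplasmic mean is zero; ratio undefined")
    return LineScanResult(
        junctional_mean=junctional_mean,
        cytoplasmic_mean=cytoplasmic_mean,
        ratio=junctional_mean / cytoplasmic_mean,
        profile=profile,
        normalized_profile=profile / cytoplasmic_mean,
    )


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------

@dataclass
class RatioSummary:
    """Per-group boxplot statistics of line-scan ratios plus group tests."""

    table: "object"            # pandas DataFrame: group, n, median, q1, q3, min, max
    comparisons: list


def aggregate_ratios(results, group_labels=None) -> RatioSummary:
    """Summarise line-scan ratios per group (boxplot statistics).

    ``results`` may be a list of :class:`LineScanResult` (or plain ratios)
    with a parallel ``group_labels`` sequence, or a mapping of group name to
    such a list.  Quartiles use linear interpolation.  Groups are compared
    pairwise with the two-sided Mann-Whitney rank-sum test.
    """
    import pandas as pd

    from .stats import compare_groups

    def _ratio(x):
        return float(x.ratio) if isinstance(x, LineScanResult) else float(x)

    if isinstance(results, dict):
        groups = {k: [_ratio(v) for v in vals] for k, vals in results.items()}
    else:
        if group_labels is None:
            groups = {"all": [_ratio(v) for v in results]}
        else:
            if len(group_labels) != len(results):
                raise ValueError("group_labels must match results in length")
            groups = {}
            for r, g in zip(results, group_labels):
                groups.setdefault(g, []).append(_ratio(r))
    for g, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"group {g!r} is empty")

    rows = []
    for g, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        rows.append({
            "group": g, "n": len(v),
            "median": float(np.median(v)),
            "q1": float(np.quantile(v, 0.25)),
            "q3": float(np.quantile(v, 0.75)),
            "min": float(v.min()), "max": float(v.max()),
        })
    table = pd.DataFrame(rows)

    comparisons = []
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            cmp = compare_groups(groups[a], groups[b], test="mann_whitney")
            cmp.group_pair = (a, b)
            comparisons.append(cmp)
    return RatioSummary(table=table, comparisons=comparisons)
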