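"""Synthetic inputs with known ground truth for every estimator.

Generators emulate the statistical structure of the assays the pipeline
quantifies:

* epithelial-monolayer immunofluorescence with border-enriched signal of
  controllable enrichment ratio and patchiness (seeded nearest-seed
  tessellation for cell shapes),
* keratin-like filament networks rendered from an explicit line arrangement
  whose exact branch/junction graph is recorded,
* AFM force-distance curves with known contact point, unbinding force and
  step position (piecewise model: linear contact ramp; on retract either a
  constant-force tether plateau — the default — or a linear ramp, ending in
  a single instantaneous rupture step),
* force maps whose per-pixel binding is Bernoulli with different
  probabilities on a junctional border stripe and the surrounding surface,
* binary dispase-well images with a known fragment count plus sub-threshold
  debris.

All randomness flows through one seeded generator per call: identical seeds
give bit-identical outputs.  Noise is additive i.i.d. Gaussian on force and
image intensity, clipped at zero for images.  Every generator returns
machine-readable ground truth sufficient to score the downstream estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import networkx as nx
from scipy import ndimage
from shapely.geometry import LineString
from shapely.ops import linemerge, unary_union
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.morphology import disk
from skimage.segmentation import find_boundaries

from .afm import AcquisitionParams, ForceDistanceCurve, ForceMap
from .core import DEFAULT_PIXEL_SIZE_UM, CellLabelMask, GeometryError, IntensityImage
from .linescan import trace_borders


# ==========================================================================
# monolayer immunofluorescence
# ==========================================================================

@dataclass
class MonolayerParams:
    """Parameters of the synthetic border-enriched monolayer image."""

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_cells: int = 6
    enrichment_ratio: float = 3.0
    patchiness: float = 0.0          # fraction of border length modulated
    patch_amplitude: float = 0.0     # multiplicative excess on patches
    cytoplasm_mean: float = 100.0
    noise_sd: float = 0.0
    border_width_px: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment_ratio < 0 or self.patch_amplitude < 0:
            raise ValueError("enrichment_ratio and patch_amplitude must be >= 0")
        if not 0 <= self.patchiness <= 1:
            raise ValueError("patchiness must lie in [0, 1]")
        if self.cytoplasm_mean <= 0 or self.noise_sd < 0:
            raise ValueError("cytoplasm_mean > 0 and noise_sd >= 0 required")
        if self.border_width_px < 1:
            raise ValueError("border_width_px must be >= 1")


@dataclass
class MonolayerTruth:
    """Ground truth accompanying a generated monolayer image."""

    enrichment_ratio: float
    seeds: np.ndarray
    border_pixels: np.ndarray      # (M, 2) coordinates of the enriched band
    patch_pixels: np.ndarray       # (K, 2) coordinates carrying patch excess
    params: MonolayerParams


def generate_monolayer(params: MonolayerParams):
    """Generate (image, cell label mask, ground truth).

    Cells are the nearest-seed (Voronoi) regions of ``n_cells`` random seed
    points; the bicellular boundary band (``border_width_px`` wide) carries
    ``enrichment_ratio`` times the cytoplasmic intensity.  A ``patchiness``
    fraction of each traced border is additionally modulated by
    ``1 + patch_amplitude`` over contiguous arcs, emulating irregularly
    clustered staining.
    """
    H, W = params.image_shape
    if H <= 0 or W <= 0:
        raise GeometryError("image must have positive area")
    if params.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if params.n_cells > (H * W) // 16:
        raise GeometryError("image too small to hold the requested seed points")
    rng = np.random.default_rng(params.rng_seed)

    margin = min(2.0, H / 4, W / 4)
    min_sep = max(4.0, 0.3 * np.sqrt(H * W / params.n_cells))
    placed: list[np.ndarray] = []
    for _ in range(200 * params.n_cells):
        cand = np.array([rng.uniform(margin, H - 1 - margin),
                         rng.uniform(margin, W - 1 - margin)])
        if all(np.linalg.norm(cand - p) >= min_sep for p in placed):
            placed.append(cand)
            if len(placed) == params.n_cells:
                break
    if len(placed) < params.n_cells:
        raise GeometryError("could not place well-separated cell seeds; "
                            "image too small for n_cells")
    seeds = np.array(placed)
    _check_seed_geometry(seeds)

    rr, cc = np.indices((H, W))
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    labels = (np.argmin(d2, axis=1) + 1).astype(np.int32).reshape(H, W)

    centerline = find_boundaries(labels, connectivity=2, mode="thick")
    r = (params.border_width_px - 1) // 2
    border_mask = ndimage.binary_dilation(centerline, structure=disk(r)) if r > 0 else centerline

    enrich = np.ones((H, W), dtype=float)
    enrich[border_mask] = params.enrichment_ratio

    patch_mask = np.zeros((H, W), dtype=bool)
    if params.patchiness > 0 and params.patch_amplitude > 0:
        for trace in trace_borders(labels):
            n_pix = len(trace)
            n_patch = int(round(params.patchiness * n_pix))
            if n_patch == 0:
                continue
            start = int(rng.integers(0, max(1, n_pix - n_patch + 1)))
            arc = trace.pixels[start:start + n_patch]
            sel = np.zeros((H, W), dtype=bool)
            sel[arc[:, 0], arc[:, 1]] = True
            sel = ndimage.binary_dilation(sel, structure=disk(max(r, 1))) & border_mask
            patch_mask |= sel
        enrich[patch_mask] *= 1.0 + params.patch_amplitude

    img = params.cytoplasm_mean * enrich
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)

    truth = MonolayerTruth(
        enrichment_ratio=params.enrichment_ratio,
        seeds=seeds,
        border_pixels=np.argwhere(border_mask),
        patch_pixels=np.argwhere(patch_mask),
        params=params,
    )
    return (IntensityImage(img, params.pixel_size_um), CellLabelMask(labels), truth)


def _check_seed_geometry(seeds: np.ndarray) -> None:
    n = len(seeds)
    d = np.sqrt(((seeds[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    if d.min() < 2.0:
        raise GeometryError("seed points coincide (closer than 2 px)")
    if n >= 3:
        centered = seeds - seeds.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[1] < 1e-6:
            raise GeometryError("seed points are collinear")


# ==========================================================================
# filament networks
# ==========================================================================

@dataclass
class FilamentNetworkParams:
    """Parameters of the synthetic keratin-like filament image."""

    image_shape: tuple[int, int] = (256, 256)
    n_seeds: int = 5
    branch_prob: float = 0.02      # per growth step
    step_len_px: float = 4.0
    filament_sigma_px: float = 1.0
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if not 0 <= self.branch_prob <= 1:
            raise ValueError("branch_prob must lie in [0, 1]")


@dataclass
class NetworkGraph:
    """The true branch/junction graph of a rendered filament arrangement.

    ``graph`` is a :class:`networkx.MultiGraph` whose nodes are branch/end
    points ((row, col) tuples) and whose edges are filament segments between
    them (attribute ``length`` in px).  ``n_edges`` counts filament
    branches, ``n_junctions`` the nodes where >= 3 branches meet.
    """

    graph: nx.MultiGraph
    edge_lines: list               # list of (row, col) vertex arrays
    n_edges: int
    n_junctions: int
    n_endpoints: int

    def coarse_counts(self, min_junction_sep_px: float) -> tuple[int, int]:
        """(n_edges, n_junctions) after merging junction pairs joined by an
        edge shorter than ``min_junction_sep_px`` — the graph at a stated
        spatial resolution, comparable with skeleton-derived counts."""
        from .skeleton import _contract_short_junction_edges

        edge_list = [(u, v, d["length"]) for u, v, d in self.graph.edges(data=True)]
        return _contract_short_junction_edges(edge_list, min_junction_sep_px)


def _build_network_graph(lines: list[LineString]) -> NetworkGraph:
    merged = unary_union(lines)
    merged = linemerge(merged) if merged.geom_type != "LineString" else merged
    if merged.geom_type == "LineString":
        geoms = [merged]
    else:
        geoms = list(merged.geoms)

    def key(pt):
        return (round(pt[0], 6), round(pt[1], 6))

    g = nx.MultiGraph()
    edge_lines = []
    for geom in geoms:
        coords = np.asarray(geom.coords)
        u, v = key(coords[0]), key(coords[-1])
        g.add_edge(u, v, length=float(geom.length))
        edge_lines.append(coords)
    n_junctions = sum(1 for _, deg in g.degree() if deg >= 3)
    n_endpoints = sum(1 for _, deg in g.degree() if deg == 1)
    return NetworkGraph(graph=g, edge_lines=edge_lines, n_edges=g.number_of_edges(),
                        n_junctions=n_junctions, n_endpoints=n_endpoints)


def _render_lines(edge_lines, image_shape, sigma, amplitude=100.0):
    H, W = image_shape
    canvas = np.zeros((H, W), dtype=float)
    for coords in edge_lines:
        for (r0, c0), (r1, c1) in zip(coords[:-1], coords[1:]):
            rr, cc = draw_line(int(round(r0)), int(round(c0)),
                               int(round(r1)), int(round(c1)))
            ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            canvas[rr[ok], cc[ok]] = 1.0
    if sigma > 0:
        canvas = ndimage.gaussian_filter(canvas, sigma)
        # normalize by the ridge peak of a single blurred 1-px line so the
        # rendered intensity of an isolated filament is `amplitude`
        probe = np.zeros((1, max(17, int(8 * sigma) | 1)))
        probe[0, probe.shape[1] // 2] = 1.0
        peak = ndimage.gaussian_filter1d(probe, sigma, axis=1).max()
        canvas /= peak
    return np.clip(canvas, 0.0, 2.0) * amplitude


def network_from_polylines(polylines, image_shape, filament_sigma_px: float = 1.2,
                           pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM):
    """Build (image, NetworkGraph) from explicit (row, col) polylines.

    Intersections between polylines become junction nodes; useful for
    constructing fixtures with hand-countable topology (e.g. two crossing
    filaments give 4 branches and 1 junction).
    """
    lines = [LineString(np.asarray(p, dtype=float)) for p in polylines]
    net = _build_network_graph(lines)
    img = _render_lines(net.edge_lines, image_shape, filament_sigma_px)
    return IntensityImage(img, pixel_size_um), net


def generate_filament_network(params: FilamentNetworkParams):
    """Grow a random filament arrangement and render it as an image.

    Filaments grow as straight rays from random anchor points in steps of
    ``step_len_px``; at each step a new branch is spawned with probability
    ``branch_prob`` at a 30-60 degree angle.  The exact geometric graph of
    the resulting line arrangement (including incidental crossings between
    filaments) is computed independently of any image processing and
    returned as ground truth.
    """
    H, W = params.image_shape
    if H <= 0 or W <= 0:
        raise GeometryError("image must have positive area")
    rng = np.random.default_rng(params.rng_seed)

    max_filaments = max(20, 3 * params.n_seeds)
    max_steps = int(2 * max(H, W) / max(params.step_len_px, 1e-6))
    # a branch (or seed filament) must reach at least this length to exist;
    # shorter stubs are below the resolution of any skeleton analysis
    min_len = 3.0 * params.step_len_px
    # filaments approaching an existing filament closer than this either
    # cross it transversally (>= 30 degrees) or terminate with a standoff
    # gap; shallow glancing passages would render as unresolvable
    # near-parallel merges
    clearance = max(3.0, 2.5 * params.filament_sigma_px)
    standoff = clearance + 2.0 * params.step_len_px
    margin = 4.0
    queue: list[tuple[np.ndarray, float, int]] = []   # (start, angle, parent idx)
    for _ in range(params.n_seeds):
        p0 = np.array([rng.uniform(margin, H - 1 - margin),
                       rng.uniform(margin, W - 1 - margin)])
        queue.append((p0, rng.uniform(0, 2 * np.pi), -1))

    from shapely.geometry import Point

    placed: list[dict] = []   # {'vertices': [...], 'ls': LineString}

    def _local_dir(ls: LineString, pt: np.ndarray) -> np.ndarray:
        s = ls.project(Point(pt))
        a = np.asarray(ls.interpolate(max(0.0, s - 0.5)).coords[0])
        b = np.asarray(ls.interpolate(min(ls.length, s + 0.5)).coords[0])
        v = b - a
        n = np.linalg.norm(v)
        return v / n if n > 0 else np.array([1.0, 0.0])

    while queue and len(placed) < max_filaments:
        start, angle, parent_idx = queue.pop(0)
        direction = np.array([np.sin(angle), np.cos(angle)])
        pos = start.copy()
        ignore = {parent_idx} if parent_idx >= 0 else set()
        positions = [start.copy()]
        spawn_candidates: list[tuple[int, np.ndarray]] = []
        blocked_by: int | None = None
        for step_i in range(max_steps):
            nxt = pos + params.step_len_px * direction
            if not (0 <= nxt[0] <= H - 1 and 0 <= nxt[1] <= W - 1):
                break
            for idx, pl in enumerate(placed):
                if idx in ignore:
                    if pl["ls"].distance(Point(pos)) > clearance:
                        ignore.discard(idx)
                    else:
                        continue
                if pl["ls"].distance(Point(nxt)) < clearance:
                    other = _local_dir(pl["ls"], nxt)
                    cosang = abs(float(np.dot(direction, other)))
                    if cosang <= np.cos(np.pi / 6):
                        ignore.add(idx)      # transversal: cross and move on
                    else:
                        blocked_by = idx     # glancing: stop short of that line
                        break
            if blocked_by is not None:
                break
            pos = nxt
            positions.append(pos.copy())
            if step_i >= 3 and rng.random() < params.branch_prob:
                spawn_candidates.append((step_i, pos.copy()))
        if blocked_by is not None:
            # back off until a clean standoff gap separates the endpoints
            target = placed[blocked_by]["ls"]
            while len(positions) > 1 and target.distance(Point(positions[-1])) < standoff:
                positions.pop()
        pos = positions[-1]
        n_steps = len(positions) - 1
        spawn_candidates = [(s, p) for s, p in spawn_candidates if s < n_steps - 1]
        if n_steps * params.step_len_px < min_len:
            continue
        vertices = [start.copy()]
        last_spawn_step = -10
        for step_i, p in spawn_candidates:
            # keep spawn points clear of the filament end and of each other
            if step_i >= n_steps - 3 or step_i - last_spawn_step < 3:
                continue
            if len(queue) + len(placed) >= max_filaments:
                break
            sign = 1.0 if rng.random() < 0.5 else -1.0
            queue.append((p, angle + sign * rng.uniform(np.pi / 6, np.pi / 3),
                          len(placed)))
            vertices.append(p)
            last_spawn_step = step_i
        vertices.append(pos.copy())
        placed.append({"vertices": vertices, "ls": LineString(np.array(vertices))})

    lines: list[LineString] = []
    for pl in placed:
        verts = [np.asarray(v, dtype=float) for v in pl["vertices"]]
        dedup = [verts[0]]
        for v in verts[1:]:
            if np.linalg.norm(v - dedup[-1]) > 1e-9:
                dedup.append(v)
        if len(dedup) >= 2:
            lines.append(LineString(np.array(dedup)))

    if not lines:
        # degenerate draw: fall back to a single short filament at the center
        center = np.array([H / 2.0, W / 2.0])
        lines = [LineString([center, center + [0.0, max(2.0, params.step_len_px)]])]

    net = _build_network_graph(lines)
    img = _render_lines(net.edge_lines, (H, W), params.filament_sigma_px)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    return IntensityImage(img), net


# ==========================================================================
# force-distance curves
# ==========================================================================

@dataclass
class CurveSimParams:
    """Parameters of one simulated retract force-distance curve.

    The retract model is piecewise: a linear contact ramp reaching the
    setpoint at full indentation, then (with ``binding``) an adhesive
    segment out to ``step_position_nm`` past the contact point — a
    near-constant-force membrane-tether plateau by default, or a linear
    ramp-to-rupture with ``tether_plateau=False`` — ending in a single
    instantaneous rupture step back to baseline.
    """

    z_length_um: float = 1.5
    setpoint_nN: float = 0.5
    pulling_speed_um_s: float = 10.0      # metadata only
    n_points: int = 1500
    baseline_noise_sd_pN: float = 0.0
    contact_stiffness_pN_per_nm: float = 10.0
    binding: bool = False
    unbinding_force_pN: float = 50.0
    step_position_nm: float = 80.0
    tether_plateau: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 50:
            raise ValueError("n_points must be >= 50")
        if self.binding:
            if self.unbinding_force_pN <= 0:
                raise ValueError("unbinding_force_pN must be > 0 when binding")
            if not 0 < self.step_position_nm < 1000 * self.z_length_um:
                raise ValueError("step_position_nm must lie in (0, z_length)")


@dataclass
class CurveTruth:
    contact_z_nm: float
    binding: bool
    force_pN: float | None
    step_position_nm: float | None     # realized on the sampling grid
    rupture_index: int | None


def generate_force_curve(params: CurveSimParams):
    """Simulate one retract curve; returns (curve, ground truth).

    The contact point sits where the linear contact ramp would cross zero
    force, i.e. at an indentation depth of setpoint / contact stiffness.
    With ``binding=False`` and zero noise the retract force is identically
    zero beyond the contact point.
    """
    z_max = 1000.0 * params.z_length_um
    z = np.linspace(0.0, z_max, params.n_points)
    contact_z = 1000.0 * params.setpoint_nN / params.contact_stiffness_pN_per_nm
    if contact_z >= z_max:
        raise ValueError("contact regime exceeds z range; increase z_length_um")
    f = np.where(z < contact_z, params.contact_stiffness_pN_per_nm * (contact_z - z), 0.0)

    truth_force = truth_step = rupture_index = None
    if params.binding:
        rupture_z = contact_z + params.step_position_nm
        in_adh = (z >= contact_z) & (z <= rupture_z)
        if params.tether_plateau:
            f[in_adh] = -params.unbinding_force_pN
        else:
            f[in_adh] = -params.unbinding_force_pN * (z[in_adh] - contact_z) / params.step_position_nm
        idx = np.flatnonzero(in_adh)
        if len(idx) == 0:
            raise ValueError("step_position_nm smaller than the sampling interval")
        rupture_index = int(idx[-1])
        truth_force = params.unbinding_force_pN
        truth_step = float(z[rupture_index] - contact_z)

    if params.baseline_noise_sd_pN > 0:
        rng = np.random.default_rng(params.rng_seed)
        f = f + rng.normal(0.0, params.baseline_noise_sd_pN, size=f.shape)

    meta = AcquisitionParams(setpoint_nN=params.setpoint_nN,
                             z_length_um=params.z_length_um,
                             pulling_speed_um_s=params.pulling_speed_um_s)
    curve = ForceDistanceCurve(z_nm=z, force_pN=f, sweep="retract", meta=meta)
    truth = CurveTruth(contact_z_nm=float(contact_z), binding=params.binding,
                       force_pN=truth_force, step_position_nm=truth_step,
                       rupture_index=rupture_index)
    return curve, truth


# ==========================================================================
# force maps
# ==========================================================================

@dataclass
class BorderStripe:
    """A straight junctional band across the mapped region.

    The stripe runs along the long (x/width) axis of the region and spans
    ``width_um`` in y, centred at ``center_um``.
    """

    center_um: float = 1.0
    width_um: float = 0.6


@dataclass
class MapSimParams:
    """Parameters of a simulated force map over a border region."""

    region_um: tuple[float, float] = (6.0, 2.0)   # (width/x, height/y)
    grid_spacing_um: float = 0.1
    border_stripe: BorderStripe = field(default_factory=BorderStripe)
    p_bind_border: float = 0.6
    p_bind_surface: float = 0.3
    curve_params: CurveSimParams = field(default_factory=CurveSimParams)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_bind_border, self.p_bind_surface):
            if not 0 <= p <= 1:
                raise ValueError("binding probabilities must lie in [0, 1]")
        if self.grid_spacing_um <= 0:
            raise ValueError("grid_spacing_um must be positive")


def generate_force_map(params: MapSimParams) -> ForceMap:
    """Simulate a force map: one curve per grid pixel, Bernoulli binding.

    The grid has round(width/spacing) x round(height/spacing) pixels (1200
    for the default 6 x 2 µm region at 0.1 µm spacing).  Pixels inside the
    border stripe bind with ``p_bind_border``, outside with
    ``p_bind_surface``.  Per-pixel binding truth is stored in
    ``ForceMap.truth``.
    """
    w_um, h_um = params.region_um
    s = params.grid_spacing_um
    nx, ny = round(w_um / s), round(h_um / s)
    if nx < 1 or ny < 1:
        raise ValueError("region smaller than one grid cell")
    if abs(nx * s - w_um) > s or abs(ny * s - h_um) > s:
        raise ValueError("grid spacing must divide region dimensions to within one cell")

    y_centers = (np.arange(ny) + 0.5) * s
    stripe = params.border_stripe
    in_stripe = np.abs(y_centers - stripe.center_um) <= stripe.width_um / 2.0
    mask = np.repeat(in_stripe[:, None], nx, axis=1)
    if not mask.any():
        raise GeometryError("border stripe does not intersect the mapped region")

    rng = np.random.default_rng(params.rng_seed)
    bind_truth = np.zeros((ny, nx), dtype=bool)
    curves = []
    for r in range(ny):
        row = []
        for c in range(nx):
            p = params.p_bind_border if mask[r, c] else params.p_bind_surface
            bound = bool(rng.random() < p)
            bind_truth[r, c] = bound
            cp = replace(params.curve_params, binding=bound,
                         rng_seed=int(rng.integers(0, 2**31 - 1)))
            curve, _ = generate_force_curve(cp)
            row.append(curve)
        curves.append(row)

    return ForceMap(curves=curves, spacing_um=s, junction_mask=mask,
                    truth={"binding": bind_truth,
                           "p_bind_border": params.p_bind_border,
                           "p_bind_surface": params.p_bind_surface})


# ==========================================================================
# dispase fragment images
# ==========================================================================

@dataclass
class FragmentSimParams:
    """Parameters of a synthetic dispase-well fragment image."""

    image_shape: tuple[int, int] = (512, 512)
    n_fragments: int = 20
    min_frag_px: int = 50
    max_frag_px: int = 400
    debris_count: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fragments < 0 or self.debris_count < 0:
            raise ValueError("counts must be >= 0")
        if not 1 <= self.min_frag_px <= self.max_frag_px:
            raise ValueError("need 1 <= min_frag_px <= max_frag_px")


def generate_fragment_image(params: FragmentSimParams):
    """Place non-touching elliptical fragments plus sub-threshold debris.

    Returns (binary image, true fragment count).  Debris components are
    strictly smaller than ``min_frag_px`` so a size filter at
    ``min_frag_px`` recovers the fragment count exactly.  Raises when the
    requested pieces cannot be placed without touching after bounded
    retries.
    """
    H, W = params.image_shape
    rng = np.random.default_rng(params.rng_seed)
    canvas = np.zeros((H, W), dtype=bool)
    blocked = np.zeros((H, W), dtype=bool)   # canvas dilated by 1: keeps pieces 8-disconnected
    struct = np.ones((3, 3), dtype=bool)

    def place(area_lo: int, area_hi: int) -> bool:
        for _ in range(2000):
            if area_hi < 5:
                # too small for an ellipse: drop a short horizontal run
                k = int(rng.integers(area_lo, area_hi + 1))
                r0 = int(rng.integers(1, H - 2))
                c0 = int(rng.integers(1, W - 1 - k))
                rr = np.full(k, r0)
                cc = c0 + np.arange(k)
                if blocked[rr, cc].any():
                    continue
                canvas[rr, cc] = True
                piece = np.zeros((H, W), dtype=bool)
                piece[rr, cc] = True
                blocked[:] |= ndimage.binary_dilation(piece, structure=struct)
                return True
            area = rng.uniform(area_lo, area_hi)
            aspect = rng.uniform(0.5, 1.0)
            b = max(1.0, np.sqrt(area / (np.pi * aspect)))
            a = max(1.0, aspect * b)
            r0 = rng.uniform(a + 2, H - a - 3)
            c0 = rng.uniform(b + 2, W - b - 3)
            rr, cc = draw_ellipse(r0, c0, a, b, shape=(H, W))
            if len(rr) < area_lo or len(rr) > area_hi:
                continue
            if blocked[rr, cc].any():
                continue
            canvas[rr, cc] = True
            piece = np.zeros((H, W), dtype=bool)
            piece[rr, cc] = True
            blocked[:] |= ndimage.binary_dilation(piece, structure=struct)
            return True
        return False

    for _ in range(params.n_fragments):
        if not place(params.min_frag_px, params.max_frag_px):
            raise GeometryError("could not place all fragments without touching; "
                                "reduce counts or sizes")
    debris_hi = max(1, min(params.min_frag_px - 1, 12))
    for _ in range(params.debris_count):
        if not place(1, debris_hi):
            raise GeometryError("could not place all debris specks without touching")
    return canvas, params.n_fragments
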