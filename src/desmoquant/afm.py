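"""AFM force-distance curve and force-map analysis.

Single desmosomal-cadherin interactions are probed by force spectroscopy
with a functionalized cantilever: each retract curve may contain a force
step where a bond ruptures.  This module locates the tip-sample contact
point, detects unbinding events (step magnitude = unbinding force, distance
from contact = step position; large step positions indicate membrane
tethers), and summarises force maps — grids of curves recorded over a small
region spanning an intercellular border — into a binding frequency and a
junctional distribution coefficient (binding frequency on the border stripe
divided by binding frequency on the surrounding surface).

Sign convention: raw curves store adhesive (downward) deflection as negative
force; reported event forces are positive magnitudes.  Only retract sweeps
are analysed.  Baseline scatter is estimated robustly with the median
absolute deviation (MAD) of the final 20% of extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import DesmoquantError

_MAD_TO_SD = 1.4826  # consistency factor for Gaussian noise


@dataclass
class AcquisitionParams:
    """Force-mapping acquisition settings (metadata)."""

    setpoint_nN: float = 0.5
    z_length_um: float = 1.5
    pulling_speed_um_s: float = 10.0
    contact_time_s: float = 0.1
    spring_constant_N_m: float = 0.03
    tip_radius_nm: float = 20.0

    def __post_init__(self) -> None:
        for name in ("setpoint_nN", "z_length_um", "pulling_speed_um_s",
                     "contact_time_s", "spring_constant_N_m", "tip_radius_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ForceDistanceCurve:
    """One sweep of force vs tip-sample displacement.

    ``z_nm`` increases from contact toward full extension for retract
    sweeps; ``force_pN`` is the cantilever force with adhesion negative.
    """

    z_nm: np.ndarray
    force_pN: np.ndarray
    sweep: str = "retract"
    meta: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self) -> None:
        self.z_nm = np.asarray(self.z_nm, dtype=float)
        self.force_pN = np.asarray(self.force_pN, dtype=float)
        if self.z_nm.shape != self.force_pN.shape or self.z_nm.ndim != 1:
            raise ValueError("z and force must be 1-D arrays of equal length")
        if len(self.z_nm) < 50:
            raise ValueError("curve too short (< 50 samples)")
        if self.sweep not in ("approach", "retract"):
            raise ValueError("sweep must be 'approach' or 'retract'")
        if np.any(np.diff(self.z_nm) < 0):
            raise ValueError("z_nm must be monotone non-decreasing")


@dataclass
class UnbindingEvent:
    """A single bond-rupture step on a retract curve."""

    force_pN: float
    step_position_nm: float
    rupture_index: int

    def __post_init__(self) -> None:
        if self.force_pN <= 0:
            raise ValueError("event force must be positive")
        if self.step_position_nm <= 0:
            raise ValueError("step position must be positive")


# --------------------------------------------------------------------------
# contact point
# --------------------------------------------------------------------------

def _baseline_stats(force: np.ndarray, fraction: float) -> tuple[float, float]:
    tail = force[int(round((1 - fraction) * len(force))):]
    b0 = float(np.median(tail))
    sigma = float(_MAD_TO_SD * np.median(np.abs(tail - b0)))
    return b0, sigma


def find_contact_point(curve: ForceDistanceCurve) -> float:
    """Locate the tip-sample contact point of a curve, in nm along z.

    A robust baseline (median of the outer 30% of extension) is intersected
    with a straight line fitted to the repulsive contact regime.  Raises
    :class:`DesmoquantError` when the curve contains no contact region
    (no sample exceeds baseline + 5 sigma).
    """
    z, f = curve.z_nm, curve.force_pN
    b0, sigma = _baseline_stats(f, 0.30)
    fmax = float(f.max())
    thresh = b0 + max(5.0 * sigma, 1e-9, 1e-6 * max(abs(fmax), 1.0))
    above = f > thresh
    if not above.any():
        raise DesmoquantError("no contact region: force never exceeds baseline + 5 sigma")
    # fit the upper part of the contact ramp for a stable slope
    fit_mask = (f - b0) > 0.25 * (fmax - b0)
    if fit_mask.sum() < 2:
        fit_mask = above
    a, c = np.polyfit(z[fit_mask], f[fit_mask], 1)
    if a >= 0:
        raise DesmoquantError("contact regime has non-negative slope; cannot extrapolate")
    return float((b0 - c) / a)


# --------------------------------------------------------------------------
# unbinding event detection
# --------------------------------------------------------------------------

def _rolling_median(x: np.ndarray, w: int) -> np.ndarray:
    from numpy.lib.stride_tricks import sliding_window_view

    return np.median(sliding_window_view(x, w), axis=-1)


def detect_unbinding_events(curve: ForceDistanceCurve, threshold_sigma: float = 6.0,
                            *, window: int = 8, pre_samples: int = 5,
                            contact_z_nm: float | None = None) -> list[UnbindingEvent]:
    """Detect unbinding (bond rupture) events on a retract curve.

    An event is a step in which the force returns toward baseline by more
    than ``threshold_sigma`` baseline standard deviations within a short
    window, after a sustained adhesive (negative) excursion of at least the
    same depth.  The event force is the post-step minus the pre-step median
    force (a positive magnitude); the step position is the distance of the
    rupture from the contact point.

    Returns an empty list when no event is found.  ``contact_z_nm`` can be
    supplied to skip re-estimating the contact point.
    """
    if curve.sweep != "retract":
        raise ValueError("unbinding events are defined on retract sweeps only")
    if not math.isfinite(threshold_sigma):
        return []
    z, f = curve.z_nm, curve.force_pN
    n = len(f)
    w = int(min(window, max(2, n // 10)))
    b0, sigma = _baseline_stats(f, 0.20)
    sigma_eff = max(sigma, 1e-9)
    g = f - b0

    # M[j] = median of g[j .. j+w-1]
    M = _rolling_median(g, w)
    # candidate rupture index i = last pre-step sample:
    #   pre_level(i)  = median g[i-w+1 .. i] = M[i-w+1]
    #   post_level(i) = median g[i+1 .. i+w] = M[i+1]
    idx = np.arange(w - 1, n - w)
    pre_lev = M[idx - w + 1]
    jump = M[idx + 1] - pre_lev
    cand = (jump > threshold_sigma * sigma_eff) & (pre_lev < -threshold_sigma * sigma_eff)
    if not cand.any():
        return []

    events: list[UnbindingEvent] = []
    cz = contact_z_nm
    # group contiguous candidates, one event per group
    cand_idx = idx[cand]
    splits = np.where(np.diff(cand_idx) > w)[0] + 1
    for grp in np.split(cand_idx, splits):
        # refine rupture to the largest single-sample rise inside the group span
        lo, hi = grp[0], min(grp[-1] + w, n - 1)
        d = np.diff(g[lo:hi + 1])
        r = int(lo + np.argmax(d))  # last sample before the step
        k = min(pre_samples, r + 1)
        pre_level = float(np.median(g[r - k + 1:r + 1]))
        post_level = float(np.median(g[r + 1:min(r + 1 + w, n)]))
        force = post_level - pre_level
        if force <= threshold_sigma * sigma_eff:
            continue
        if cz is None:
            try:
                cz = find_contact_point(curve)
            except DesmoquantError:
                # no repulsive contact regime on this curve; cannot place events
                return []
        step_pos = float(z[r] - cz)
        if step_pos <= 0:
            continue
        events.append(UnbindingEvent(force_pN=force, step_position_nm=step_pos,
                                     rupture_index=r))
    return events


# --------------------------------------------------------------------------
# force maps
# --------------------------------------------------------------------------

@dataclass
class ForceMap:
    """A grid of force-distance curves over a border region.

    ``curves`` is a (rows, cols) nested list of retract
    :class:`ForceDistanceCurve`; ``junction_mask`` marks the border stripe.
    ``events`` is filled by :func:`analyze_map` (per-pixel event lists).
    """

    curves: list            # nested [row][col]
    spacing_um: float
    junction_mask: np.ndarray
    events: list | None = None
    truth: dict | None = None   # ground truth when synthetic

    def __post_init__(self) -> None:
        self.junction_mask = np.asarray(self.junction_mask, dtype=bool)
        rows = len(self.curves)
        cols = len(self.curves[0]) if rows else 0
        if self.junction_mask.shape != (rows, cols):
            raise ValueError("junction mask shape must match the curve grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.junction_mask.shape

    @property
    def n_curves(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class MapStatistics:
    binding_frequency: float
    binding_frequency_border: float
    binding_frequency_surface: float
    distribution_coefficient: float | None
    n_border_px: int
    n_surface_px: int


def analyze_map(fmap: ForceMap, threshold_sigma: float = 6.0) -> ForceMap:
    """Run event detection on every pixel of a force map (idempotent)."""
    if fmap.events is not None:
        return fmap
    rows, cols = fmap.shape
    events = [[detect_unbinding_events(fmap.curves[r][c], threshold_sigma)
               for c in range(cols)] for r in range(rows)]
    fmap.events = events
    return fmap


def map_statistics(fmap: ForceMap, threshold_sigma: float = 6.0) -> MapStatistics:
    """Binding frequency and junctional distribution coefficient of a map.

    Binding frequency is the fraction of pixels whose curve contains at
    least one unbinding event, computed overall, on the border stripe and on
    the surrounding surface.  The distribution coefficient is
    BF_border / BF_surface; when BF_surface is zero it is reported as
    ``None`` (undefined) together with the pixel counts.
    """
    mask = fmap.junction_mask
    n_border = int(mask.sum())
    n_surface = int((~mask).sum())
    if n_border == 0 or n_surface == 0:
        raise DesmoquantError("junction mask must contain border and surface pixels")
    analyze_map(fmap, threshold_sigma)
    bound = np.array([[len(ev) > 0 for ev in row] for row in fmap.events], dtype=bool)
    bf = float(bound.mean())
    bf_border = float(bound[mask].mean())
    bf_surface = float(bound[~mask].mean())
    coeff = bf_border / bf_surface if bf_surface > 0 else None
    return MapStatistics(
        binding_frequency=bf,
        binding_frequency_border=bf_border,
        binding_frequency_surface=bf_surface,
        distribution_coefficient=coeff,
        n_border_px=n_border,
        n_surface_px=n_surface,
    )


def pool_events(maps, group_labels=None, threshold_sigma: float = 6.0):
    """Pool per-event forces and step positions from several maps.

    Returns a long-format :class:`pandas.DataFrame` with one row per
    detected event (columns: group, map_index, row, col, force_pN,
    step_position_nm).  Pooling is order-invariant up to row order.
    """
    import pandas as pd

    if group_labels is None:
        group_labels = ["all"] * len(maps)
    if len(group_labels) != len(maps):
        raise ValueError("group_labels must match maps in length")
    rows = []
    for m_i, (fmap, grp) in enumerate(zip(maps, group_labels)):
        analyze_map(fmap, threshold_sigma)
        for r in range(fmap.shape[0]):
            for c in range(fmap.shape[1]):
                for ev in fmap.events[r][c]:
                    rows.append({"group": grp, "map_index": m_i, "row": r, "col": c,
                                 "force_pN": ev.force_pN,
                                 "step_position_nm": ev.step_position_nm})
    return pd.DataFrame(rows, columns=["group", "map_index", "row", "col",
                                       "force_pN", "step_position_nm"])
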