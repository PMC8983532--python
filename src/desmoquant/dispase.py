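"""Dispase-assay fragment counting.

After enzymatic detachment and mechanical stress, the number of monolayer
fragments per well inversely reflects intercellular adhesive strength (the
hyperadhesion variant adds an EGTA incubation before the stress but is
quantified identically).  Fragments are 8-connected foreground components;
components smaller than ``min_size_px`` are discarded as debris, a
disclosed stand-in for the by-eye exclusion of specks during manual
counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import as_pixels
from .skeleton import BinaryImage, binarize

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class FragmentCount:
    well_id: str | None
    n_fragments: int
    min_size_px: int
    component_sizes: list = field(default_factory=list)
    labeled: np.ndarray | None = None


def count_fragments(image, threshold: float | None = None,
                    min_size_px: int = 50, well_id: str | None = None) -> FragmentCount:
    """Count monolayer fragments in a well image.

    ``image`` may be a boolean mask or an intensity image; intensity input
    is thresholded at ``threshold`` (Otsu when omitted).  Components are
    8-connected; ``component_sizes`` lists all component sizes before the
    size filter, ``n_fragments`` the number of components of at least
    ``min_size_px`` pixels.
    """
    if isinstance(image, BinaryImage):
        mask = image.mask
    else:
        arr = np.asarray(image.pixels if hasattr(image, "pixels") else image)
        if arr.dtype == bool:
            mask = arr
        else:
            method = "fixed" if threshold is not None else "otsu"
            mask = binarize(as_pixels(image), method=method, threshold=threshold).mask
    if mask.size == 0:
        raise ValueError("empty image")

    labeled, n = ndimage.label(mask, structure=_STRUCT8)
    sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1)).astype(int)
    n_frag = int(np.count_nonzero(sizes >= min_size_px))
    return FragmentCount(well_id=well_id, n_fragments=n_frag, min_size_px=min_size_px,
                         component_sizes=sizes.tolist(), labeled=labeled)


@dataclass
class ComparisonTable:
    table: "object"        # pandas DataFrame: group, n, mean, sem
    comparisons: list


def compare_conditions(counts: dict) -> ComparisonTable:
    """Per-condition mean ± SEM of fragment counts and pairwise t tests.

    ``counts`` maps condition name to a list of :class:`FragmentCount` (or
    plain integers), one per well.  SEM for a group with fewer than 2 wells
    is reported as NaN.  Requires at least 2 conditions.
    """
    import pandas as pd

    from .stats import compare_groups

    if len(counts) < 2:
        raise ValueError("need at least 2 conditions to compare")

    def _vals(entries):
        return np.array([e.n_fragments if isinstance(e, FragmentCount) else int(e)
                         for e in entries], dtype=float)

    groups = {g: _vals(v) for g, v in counts.items()}
    rows = []
    for g, v in groups.items():
        if len(v) == 0:
            raise ValueError(f"condition {g!r} has no wells")
        sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) >= 2 else float("nan")
        rows.append({"group": g, "n": len(v), "mean": float(v.mean()), "sem": sem})
    table = pd.DataFrame(rows)

    comparisons = []
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if len(groups[a]) >= 2 and len(groups[b]) >= 2:
                cmp = compare_groups(groups[a], groups[b], test="student_t")
                cmp.group_pair = (a, b)
                comparisons.append(cmp)
    return ComparisonTable(table=table, comparisons=comparisons)
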