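"""Irregularity score for membrane staining along a cell border.

The score measures how dominant supra-average intensities are along a traced
membrane: for each border pixel the excess of its intensity over the border
mean x̄ is taken (pixels at or below x̄ contribute zero), the excesses are
averaged over all N pixels, and the result is divided by x̄ to normalize for
staining strength::

    score = [ (1/N) * sum_i max(I_i - x̄, 0) ] / x̄

A score of 0 means every pixel has the same intensity; patchy, clustered
staining gives larger scores.  The score is invariant to multiplying all
intensities by a positive constant, and depends only on the multiset of
intensities — it quantifies amplitude dispersion, not spatial frequency (a
shuffled profile scores identically).

The averaging denominator is read as "all N border pixels"; the variant that
averages only over supra-average pixels is available via
``denominator='bright_pixels'``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import DesmoquantError, as_pixels
from .linescan import BorderTrace, _local_frame


@dataclass
class BorderProfile:
    """Ordered intensity samples I_1..I_N along one membrane trace."""

    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ValueError("border profile must be 1-D")
        if len(self.intensities) < 2:
            raise ValueError("border profile needs at least 2 samples")
        if np.any(self.intensities < 0) or not np.all(np.isfinite(self.intensities)):
            raise ValueError("border profile intensities must be finite and >= 0")

    @property
    def n_pixels(self) -> int:
        return len(self.intensities)

    @property
    def mean_intensity(self) -> float:
        return float(self.intensities.mean())


@dataclass
class IrregularityScore:
    score: float
    n_pixels: int
    mean_intensity: float
    denominator: str = "all_pixels"


def irregularity_score(profile, denominator: str = "all_pixels") -> IrregularityScore:
    """Compute the irregularity score of a border intensity profile.

    Parameters
    ----------
    profile
        A :class:`BorderProfile` or a 1-D sequence of intensities.
    denominator
        ``'all_pixels'`` (default) averages the one-sided excesses over all N
        border pixels; ``'bright_pixels'`` averages only over the pixels that
        exceed the mean.
    """
    if not isinstance(profile, BorderProfile):
        profile = BorderProfile(np.asarray(profile, dtype=float))
    I = profile.intensities
    xbar = profile.mean_intensity
    if xbar <= 0:
        raise DesmoquantError("mean border intensity is zero; score undefined")
    excess = np.maximum(I - xbar, 0.0)
    if denominator == "all_pixels":
        mean_dev = excess.mean()
    elif denominator == "bright_pixels":
        n_bright = int(np.count_nonzero(I > xbar))
        mean_dev = excess.sum() / n_bright if n_bright else 0.0
    else:
        raise ValueError("denominator must be 'all_pixels' or 'bright_pixels'")
    return IrregularityScore(
        score=float(mean_dev / xbar),
        n_pixels=profile.n_pixels,
        mean_intensity=xbar,
        denominator=denominator,
    )


def border_irregularity(image, trace: BorderTrace, width_px: int = 3,
                        denominator: str = "all_pixels") -> IrregularityScore:
    """Irregularity score of a traced border in an image.

    At every trace pixel the intensity is averaged over ``width_px`` samples
    taken along the local border normal (bilinear interpolation), giving one
    profile value per border pixel; the score of that profile is returned.
    """
    pixels = as_pixels(image)
    path = trace.pixels
    if len(path) < 2:
        raise DesmoquantError("trace too short for a border profile")
    woff = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0
    values = np.empty(len(path), dtype=float)
    for i in range(len(path)):
        _, normal = _local_frame(path, i)
        pts = path[i].astype(float)[None, :] + woff[:, None] * normal[None, :]
        r = np.clip(pts[:, 0], 0, pixels.shape[0] - 1)
        c = np.clip(pts[:, 1], 0, pixels.shape[1] - 1)
        values[i] = ndimage.map_coordinates(pixels, [r, c], order=1, mode="nearest").mean()
    return irregularity_score(BorderProfile(values), denominator=denominator)
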