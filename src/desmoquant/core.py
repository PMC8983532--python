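"""Shared containers and errors.

Images are plain 2-D numpy arrays wrapped with the physical pixel size so
that densities and step positions come out in µm / nm.  The default pixel
size (0.161 µm) matches the widefield acquisition settings used for all
intensity quantifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default physical pixel size of the quantification micrographs, µm/pixel
DEFAULT_PIXEL_SIZE_UM = 0.161


class DesmoquantError(Exception):
    """Base class for all errors raised by desmoquant."""


class GeometryError(DesmoquantError):
    """Degenerate geometry (coincident/collinear seeds, empty regions...)."""


class ThresholdError(DesmoquantError):
    """Automatic thresholding is impossible on the given image."""


@dataclass
class IntensityImage:
    """A single-channel micrograph with a physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of non-negative, finite intensities.
    pixel_size_um
        Physical edge length of one pixel in µm.
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise ValueError("image contains negative intensities")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class CellLabelMask:
    """Integer label image: 0 = background, k > 0 = cell k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label mask must be integer-typed")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def cell_labels(self) -> np.ndarray:
        labs = np.unique(self.labels)
        return labs[labs > 0]


def as_pixels(image) -> np.ndarray:
    """Accept an IntensityImage or a bare array and return the pixel array."""
    if isinstance(image, IntensityImage):
        return image.pixels
    return np.asarray(image, dtype=float)


def as_labels(mask) -> np.ndarray:
    if isinstance(mask, CellLabelMask):
        return mask.labels
    arr = np.asarray(mask)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("label mask must be integer-typed")
    return arr
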