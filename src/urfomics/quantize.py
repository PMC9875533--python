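"""Gray-level discretization of ROI intensities.

All texture matrices are defined on a small set of gray levels 1..Ng.
Intensities are binned with a fixed number of equal-width bins spanning
the foreground intensity range of each image, which keeps features
comparable across images with different dynamic ranges.

Binning convention: with w = (max - min) / n_bins, a value x maps to
level ceil((x - min) / w), clipped to [1, n_bins].  The minimum maps to
level 1 and the maximum falls in the last bin (top edge closed), so every
foreground pixel receives a level.  Constant ROIs map to a single level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import RoiImage

__all__ = ["QuantizedRoi", "discretize"]


@dataclass(frozen=True)
class QuantizedRoi:
    """Discretized ROI: integer levels 1..n_levels on the mask foreground.

    ``levels`` is 0 outside the mask; the background carries no level.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int

    def __post_init__(self) -> None:
        fg = self.levels[self.mask]
        if fg.size == 0:
            raise ValueError("empty ROI")
        if fg.min() < 1 or fg.max() > self.n_levels:
            raise ValueError("foreground levels outside [1, n_levels]")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def discretize(image: RoiImage, n_bins: int = 32) -> QuantizedRoi:
    """Equal-width binning of foreground intensities into at most n_bins levels."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    fg = image.foreground
    lo, hi = float(fg.min()), float(fg.max())
    levels = np.zeros(image.pixels.shape, dtype=np.int64)
    if hi == lo:  # constant ROI: single level
        levels[image.mask] = 1
        return QuantizedRoi(levels=levels, mask=image.mask, n_levels=1)
    width = (hi - lo) / n_bins
    lv = np.ceil((image.pixels - lo) / width)
    lv = np.clip(lv, 1, n_bins).astype(np.int64)
    levels[image.mask] = lv[image.mask]
    return QuantizedRoi(
        levels=levels, mask=image.mask, n_levels=int(levels.max())
    )
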