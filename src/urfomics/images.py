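"""Grayscale images with binary regions of interest.

The unit of radiomic feature extraction is an :class:`RoiImage`: a 2-D
non-negative intensity grid plus a same-shape binary mask marking the
tumour region.  Masks are produced upstream (by a segmentation model or a
radiologist) and are consumed here as plain raster files; any nonzero mask
pixel counts as foreground.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["RoiImage", "load_roi_image", "find_image_mask_pairs"]


@dataclass(frozen=True)
class RoiImage:
    """A 2-D grayscale image together with a binary ROI mask.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities.
    mask
        2-D boolean array of the same shape; True marks foreground.
        Must contain at least one foreground pixel.
    pixel_spacing
        Optional (row, col) physical spacing; informational only (it
        scales first-order TotalEnergy and nothing else).
    """

    pixels: np.ndarray
    mask: np.ndarray
    pixel_spacing: tuple[float, float] | None = None
    image_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=float)
        mask = np.asarray(self.mask) != 0
        if pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {pixels.shape}")
        if pixels.shape != mask.shape:
            raise ValueError(
                f"image shape {pixels.shape} != mask shape {mask.shape}"
            )
        if not mask.any():
            raise ValueError("empty ROI: mask has no foreground pixels")
        if not np.isfinite(pixels[mask]).all():
            raise ValueError("non-finite intensity inside ROI")
        object.__setattr__(self, "pixels", pixels)
        object.__setattr__(self, "mask", mask)

    @property
    def foreground(self) -> np.ndarray:
        """1-D array of intensities inside the ROI."""
        return self.pixels[self.mask]


def _read_gray(path: Path | str) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A) written by generic viewers
        arr = arr[..., :3].mean(axis=-1)
    return np.asarray(arr, dtype=float)


def load_roi_image(
    image_path: Path | str,
    mask_path: Path | str,
    image_id: str = "",
    patient_id: str = "",
) -> RoiImage:
    """Read an image/mask pair (PNG or TIFF, 8- or 16-bit) from disk."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    return RoiImage(
        pixels=_read_gray(image_path),
        mask=_read_gray(mask_path) != 0,
        image_id=image_id or image_path.stem,
        patient_id=patient_id,
    )


def find_image_mask_pairs(
    image_dir: Path | str, mask_dir: Path | str
) -> list[tuple[Path, Path]]:
    """Pair images with masks by file stem; raise if a mask is missing."""
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    exts = {".png", ".tif", ".tiff"}
    pairs = []
    for img in sorted(p for p in image_dir.iterdir() if p.suffix.lower() in exts):
        candidates = [mask_dir / (img.stem + ext) for ext in (img.suffix, ".png", ".tif", ".tiff")]
        mask = next((c for c in candidates if c.exists()), None)
        if mask is None:
            raise FileNotFoundError(f"no mask found for image {img.name}")
        pairs.append((img, mask))
    if not pairs:
        raise FileNotFoundError(f"no images found in {image_dir}")
    return pairs
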