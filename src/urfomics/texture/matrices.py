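"""Texture matrices: GLSZM, GLRLM, GLCM and GLDM.

All four matrices are computed on a :class:`~urfomics.quantize.QuantizedRoi`
with gray levels 1..Ng restricted to the mask foreground.  Conventions:

* coordinates are (row, col), 0-based, row-major;
* GLSZM zones are connected components of equal gray level (8-connectivity
  by default, 4 optional);
* GLRLM runs are maximal colinear sequences of equal gray level along one
  of the four 2-D directions 0/45/90/135 degrees; runs break at mask
  boundaries;
* GLCM counts symmetric co-occurrences at distance 1 along the same four
  directions, both pixels inside the mask;
* GLDM dependence of a pixel is the number of its 8-neighbours inside the
  mask whose gray level differs by at most ``alpha`` (default 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..quantize import QuantizedRoi

__all__ = [
    "TextureMatrix",
    "GLRLM_ANGLES",
    "compute_glszm",
    "compute_glrlm",
    "compute_glcm",
    "compute_gldm",
]

#: direction name -> (row step, col step) for distance-1 offsets
GLRLM_ANGLES: dict[str, tuple[int, int]] = {
    "0": (0, 1),
    "45": (-1, 1),
    "90": (-1, 0),
    "135": (-1, -1),
}


@dataclass(frozen=True)
class TextureMatrix:
    """A gray level texture matrix ``counts[i-1, j-1]`` for levels i, sizes j."""

    kind: str  # GLSZM | GLRLM | GLCM | GLDM
    counts: np.ndarray  # (Ng, Nj), non-negative
    direction: str = ""  # angle tag for directional kinds

    def __post_init__(self) -> None:
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("texture matrix counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError("connectivity must be 4 or 8")


def compute_glszm(q: QuantizedRoi, connectivity: int = 8) -> TextureMatrix:
    """Count connected zones of each gray level by zone size.

    counts[i-1, s-1] = number of connected zones of level i and size s.
    Satisfies sum_{i,s} s * counts = number of foreground pixels.
    """
    structure = _structure(connectivity)
    max_size = q.n_pixels
    counts = np.zeros((q.n_levels, max_size), dtype=np.int64)
    for level in range(1, q.n_levels + 1):
        labeled, n_zones = ndimage.label(q.levels == level, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            counts[level - 1, s - 1] += 1
    # trim empty trailing size columns (keeps matrices small)
    last = int(np.nonzero(counts.any(axis=0))[0][-1]) + 1
    return TextureMatrix(kind="GLSZM", counts=counts[:, :last])


def _mask_lines(q: QuantizedRoi, angle: str):
    """Yield 1-D level sequences (0 = background) along an angle's lines."""
    lv = q.levels
    if angle == "0":
        yield from lv
    elif angle == "90":
        yield from lv.T
    elif angle == "135":  # down-right diagonals (same runs as up-left)
        for off in range(-lv.shape[0] + 1, lv.shape[1]):
            yield np.diagonal(lv, offset=off)
    elif angle == "45":  # up-right diagonals
        flipped = np.flipud(lv)
        for off in range(-flipped.shape[0] + 1, flipped.shape[1]):
            yield np.diagonal(flipped, offset=off)
    else:
        raise ValueError(f"unknown GLRLM angle {angle!r}")


def _run_lengths(line: np.ndarray):
    """Run-length encode one line; background (0) breaks runs."""
    line = np.asarray(line)
    if line.size == 0:
        return
    change = np.nonzero(np.diff(line))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [line.size]))
    for a, b in zip(starts, ends):
        if line[a] != 0:
            yield int(line[a]), int(b - a)


def compute_glrlm(
    q: QuantizedRoi, angles: tuple[str, ...] = ("0", "45", "90", "135")
) -> list[TextureMatrix]:
    """Per angle, count maximal runs of each gray level by run length."""
    if not angles:
        raise ValueError("at least one angle required")
    out = []
    for angle in angles:
        if angle not in GLRLM_ANGLES:
            raise ValueError(f"unknown GLRLM angle {angle!r}")
        counts = np.zeros((q.n_levels, q.n_pixels), dtype=np.int64)
        for line in _mask_lines(q, angle):
            for level, length in _run_lengths(line):
                counts[level - 1, length - 1] += 1
        last = int(np.nonzero(counts.any(axis=0))[0][-1]) + 1
        out.append(TextureMatrix(kind="GLRLM", counts=counts[:, :last], direction=angle))
    return out


def compute_glcm(
    q: QuantizedRoi, angles: tuple[str, ...] = ("0", "45", "90", "135")
) -> list[TextureMatrix]:
    """Symmetric distance-1 gray level co-occurrence counts per angle."""
    if not angles:
        raise ValueError("at least one angle required")
    lv, mask = q.levels, q.mask
    nrow, ncol = lv.shape
    out = []
    for angle in angles:
        dr, dc = GLRLM_ANGLES[angle]
        counts = np.zeros((q.n_levels, q.n_levels), dtype=np.int64)
        r0a, r0b = max(0, -dr), min(nrow, nrow - dr)
        c0a, c0b = max(0, -dc), min(ncol, ncol - dc)
        a = lv[r0a:r0b, c0a:c0b]
        b = lv[r0a + dr : r0b + dr, c0a + dc : c0b + dc]
        valid = mask[r0a:r0b, c0a:c0b] & mask[r0a + dr : r0b + dr, c0a + dc : c0b + dc]
        if valid.any():
            np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
        counts = counts + counts.T  # symmetrize
        out.append(TextureMatrix(kind="GLCM", counts=counts, direction=angle))
    return out


def compute_gldm(q: QuantizedRoi, alpha: int = 0) -> TextureMatrix:
    """Gray level dependence counts.

    counts[i-1, j-1] = number of foreground pixels of level i whose
    dependence (count of 8-neighbours in the mask within ``alpha`` gray
    levels) equals j-1; the dependence index j runs 1..9.
    """
    lv, mask = q.levels, q.mask
    nrow, ncol = lv.shape
    dep = np.zeros(lv.shape, dtype=np.int64)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            r0a, r0b = max(0, -dr), min(nrow, nrow - dr)
            c0a, c0b = max(0, -dc), min(ncol, ncol - dc)
            here = np.zeros(lv.shape, dtype=bool)
            a = lv[r0a:r0b, c0a:c0b]
            b = lv[r0a + dr : r0b + dr, c0a + dc : c0b + dc]
            ok = (
                mask[r0a:r0b, c0a:c0b]
                & mask[r0a + dr : r0b + dr, c0a + dc : c0b + dc]
                & (np.abs(a - b) <= alpha)
            )
            here[r0a:r0b, c0a:c0b] = ok
            dep += here
    counts = np.zeros((q.n_levels, 9), dtype=np.int64)
    np.add.at(counts, (lv[mask] - 1, dep[mask]), 1)
    last = int(np.nonzero(counts.any(axis=0))[0][-1]) + 1
    return TextureMatrix(kind="GLDM", counts=counts[:, :last])
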