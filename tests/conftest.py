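import numpy as np
import pandas as pd
import pytest

from urfomics.images import RoiImage
from urfomics.quantize import QuantizedRoi


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_quantized(rng, shape=(8, 8), n_levels=4, mask_prob=0.8) -> QuantizedRoi:
    """A random small quantized ROI with a random (non-empty) mask."""
    mask = rng.random(shape) < mask_prob
    if not mask.any():
        mask[0, 0] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return QuantizedRoi(levels=levels, mask=mask, n_levels=n_levels)


def random_roi_image(rng, shape=(16, 16)) -> RoiImage:
    mask = rng.random(shape) < 0.85
    if not mask.any():
        mask[0, 0] = True
    return RoiImage(pixels=rng.integers(0, 256, shape).astype(float), mask=mask)


@pytest.fixture
def gaussian_table():
    """Two-class feature table: 8 shifted features among 20, n=60/60."""
    rng = np.random.default_rng(7)
    n = 60
    shifted = [f"f{j:02d}" for j in range(8)]
    cols = [f"f{j:02d}" for j in range(20)]
    data = {}
    for j, c in enumerate(cols):
        neg = rng.normal(10.0, 1.0, n)
        pos = rng.normal(12.0 if c in shifted else 10.0, 1.0, n)
        data[c] = np.concatenate([pos, neg])
    table = pd.DataFrame(data)
    table["label"] = ["positive"] * n + ["negative"] * n
    table["patient_id"] = [f"p{i}" for i in range(2 * n)]
    return table, shifted
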