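"""Radiomic feature formulas for the five intensity/texture families.

86 features in total: first-order statistics (18), gray level
co-occurrence matrix (22), gray level dependence matrix (14), gray level
run length matrix (16) and gray level size zone matrix (16).  Formulas
follow the community standard definitions used by mainstream radiomics
toolkits; directional families (GLCM, GLRLM) are computed per angle and
averaged over angles.

Logs use base 2 with an epsilon of 2.2e-16 added inside the log only, so
zero-probability cells contribute nothing while nonzero cells are
unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..images import RoiImage
from ..quantize import QuantizedRoi, discretize
from .matrices import TextureMatrix, compute_glcm, compute_gldm, compute_glrlm, compute_glszm

__all__ = [
    "ExtractionConfig",
    "FEATURE_NAMES",
    "FAMILY_COUNTS",
    "first_order_features",
    "glcm_features",
    "gldm_features",
    "glrlm_features",
    "glszm_features",
    "extract_features",
]

EPS = 2.2e-16


def _log2(x: np.ndarray) -> np.ndarray:
    return np.log2(x + EPS)


@dataclass(frozen=True)
class ExtractionConfig:
    """Settings shared by all feature families.

    The gray-level discretization (fixed bin count, equal-width bins over
    the per-image foreground range), the zone connectivity and the
    per-angle-then-average aggregation are conventions, not values fixed
    by the method itself; they are therefore explicit here.
    """

    n_bins: int = 32
    connectivity: int = 8  # GLSZM zone connectivity: 4 or 8
    angles: tuple[str, ...] = ("0", "45", "90", "135")
    gldm_alpha: int = 0


# ---------------------------------------------------------------------------
# first order (18)

def first_order_features(image: RoiImage, q: QuantizedRoi) -> dict[str, float]:
    x = image.foreground
    n = x.size
    spacing = image.pixel_spacing or (1.0, 1.0)
    pixel_area = float(spacing[0]) * float(spacing[1])
    mean = float(x.mean())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    var = float(((x - mean) ** 2).mean())
    m2 = var
    if m2 > 0:
        m3 = float(((x - mean) ** 3).mean())
        m4 = float(((x - mean) ** 4).mean())
        skew = m3 / m2**1.5
        kurt = m4 / m2**2  # non-excess (Fisher-Pearson, uncorrected)
    else:
        skew = kurt = 0.0
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    hist = np.bincount(q.levels[q.mask], minlength=q.n_levels + 1)[1:]
    p = hist / n
    return {
        "Energy": float((x**2).sum()),
        "TotalEnergy": pixel_area * float((x**2).sum()),
        "Entropy": float(-(p * _log2(p)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# GLCM (22)

def _glcm_features_single(m: TextureMatrix) -> dict[str, float]:
    counts = np.asarray(m.counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty GLCM")
    P = counts / total
    ng = P.shape[0]
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ng + 1)[None, :]
    px = P.sum(axis=1)
    mu = float((i * P).sum())  # == mean of py by symmetry
    sigma2 = float((px * (np.arange(1, ng + 1) - mu) ** 2).sum())
    # diagonal and cross-diagonal distributions
    ks_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([P[(i + j) == k].sum() for k in ks_sum])
    ks_diff = np.arange(0, ng)
    p_diff = np.array([P[np.abs(i - j) == k].sum() for k in ks_diff])
    da = float((ks_diff * p_diff).sum())
    hx = float(-(px * _log2(px)).sum())
    hxy = float(-(P * _log2(P)).sum())
    pxpy = px[:, None] * px[None, :]
    hxy1 = float(-(P * _log2(pxpy)).sum())
    hxy2 = float(-(pxpy * _log2(pxpy)).sum())
    if hx > 0:
        imc1 = (hxy - hxy1) / hx
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    corr = 1.0 if sigma2 == 0 else (float((i * j * P).sum()) - mu * mu) / sigma2
    off = np.abs(i - j) > 0
    return {
        "Autocorrelation": float((i * j * P).sum()),
        "JointAverage": mu,
        "ClusterProminence": float((((i + j) - 2 * mu) ** 4 * P).sum()),
        "ClusterShade": float((((i + j) - 2 * mu) ** 3 * P).sum()),
        "ClusterTendency": float((((i + j) - 2 * mu) ** 2 * P).sum()),
        "Contrast": float(((i - j) ** 2 * P).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(p_diff * _log2(p_diff)).sum()),
        "DifferenceVariance": float(((ks_diff - da) ** 2 * p_diff).sum()),
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float((P / (1.0 + (i - j) ** 2)).sum()),
        "Idmn": float((P / (1.0 + ((i - j) / ng) ** 2)).sum()),
        "Id": float((P / (1.0 + np.abs(i - j))).sum()),
        "Idn": float((P / (1.0 + np.abs(i - j) / ng)).sum()),
        "InverseVariance": float((P[off] / (i - j)[off] ** 2).sum()) if off.any() else 0.0,
        "MaximumProbability": float(P.max()),
        "SumEntropy": float(-(p_sum * _log2(p_sum)).sum()),
        "SumSquares": float((((i - mu) ** 2) * P).sum()),
    }


def _average(dicts: list[dict[str, float]]) -> dict[str, float]:
    keys = dicts[0].keys()
    return {k: float(np.mean([d[k] for d in dicts])) for k in keys}


def glcm_features(ms: list[TextureMatrix]) -> dict[str, float]:
    """22 co-occurrence features, computed per angle then averaged."""
    nonempty = [m for m in ms if m.total > 0]
    if not nonempty:
        raise ValueError("all GLCM matrices empty")
    return _average([_glcm_features_single(m) for m in nonempty])


# ---------------------------------------------------------------------------
# GLDM (14)

def gldm_features(m: TextureMatrix) -> dict[str, float]:
    counts = np.asarray(m.counts, dtype=float)
    nz = counts.sum()
    if nz == 0:
        raise ValueError("empty GLDM")
    P = counts / nz
    ng, nd = P.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nd + 1)[None, :]
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float((i * P).sum())
    mu_j = float((j * P).sum())
    return {
        "SmallDependenceEmphasis": float((P / j**2).sum()),
        "LargeDependenceEmphasis": float((P * j**2).sum()),
        "GrayLevelNonUniformity": float((counts.sum(axis=1) ** 2).sum() / nz),
        "DependenceNonUniformity": float((counts.sum(axis=0) ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((counts.sum(axis=0) ** 2).sum() / nz**2),
        "GrayLevelVariance": float((pi * (np.arange(1, ng + 1) - mu_i) ** 2).sum()),
        "DependenceVariance": float((pj * (np.arange(1, nd + 1) - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(P * _log2(P)).sum()),
        "LowGrayLevelEmphasis": float((P / i**2).sum()),
        "HighGrayLevelEmphasis": float((P * i**2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (i**2 * j**2)).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((P * i**2 / j**2).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((P * j**2 / i**2).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((P * i**2 * j**2).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM (16)

def _glrlm_features_single(m: TextureMatrix) -> dict[str, float]:
    counts = np.asarray(m.counts, dtype=float)
    nr = counts.sum()
    if nr == 0:
        raise ValueError("empty GLRLM")
    P = counts / nr
    ng, nl = P.shape
    i = np.arange(1, ng + 1)[:, None]
    l = np.arange(1, nl + 1)[None, :]
    pi = P.sum(axis=1)
    pl = P.sum(axis=0)
    mu_i = float((i * P).sum())
    mu_l = float((l * P).sum())
    np_pixels = float((counts * l).sum())  # run conservation: sum l*counts = Np
    return {
        "ShortRunEmphasis": float((P / l**2).sum()),
        "LongRunEmphasis": float((P * l**2).sum()),
        "GrayLevelNonUniformity": float((counts.sum(axis=1) ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((counts.sum(axis=1) ** 2).sum() / nr**2),
        "RunLengthNonUniformity": float((counts.sum(axis=0) ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((counts.sum(axis=0) ** 2).sum() / nr**2),
        "RunPercentage": float(nr / np_pixels),
        "GrayLevelVariance": float((pi * (np.arange(1, ng + 1) - mu_i) ** 2).sum()),
        "RunVariance": float((pl * (np.arange(1, nl + 1) - mu_l) ** 2).sum()),
        "RunEntropy": float(-(P * _log2(P)).sum()),
        "LowGrayLevelRunEmphasis": float((P / i**2).sum()),
        "HighGrayLevelRunEmphasis": float((P * i**2).sum()),
        "ShortRunLowGrayLevelEmphasis": float((P / (i**2 * l**2)).sum()),
        "ShortRunHighGrayLevelEmphasis": float((P * i**2 / l**2).sum()),
        "LongRunLowGrayLevelEmphasis": float((P * l**2 / i**2).sum()),
        "LongRunHighGrayLevelEmphasis": float((P * i**2 * l**2).sum()),
    }


def glrlm_features(ms: list[TextureMatrix]) -> dict[str, float]:
    """16 run-length features, computed per direction then averaged."""
    nonempty = [m for m in ms if m.total > 0]
    if not nonempty:
        raise ValueError("all GLRLM matrices empty")
    return _average([_glrlm_features_single(m) for m in nonempty])


# ---------------------------------------------------------------------------
# GLSZM (16)

def glszm_features(m: TextureMatrix) -> dict[str, float]:
    counts = np.asarray(m.counts, dtype=float)
    nz = counts.sum()
    if nz == 0:
        raise ValueError("empty GLSZM")
    P = counts / nz
    ng, ns = P.shape
    i = np.arange(1, ng + 1)[:, None]
    s = np.arange(1, ns + 1)[None, :]
    pi = P.sum(axis=1)
    ps = P.sum(axis=0)
    mu_i = float((i * P).sum())
    mu_s = float((s * P).sum())
    np_pixels = float((counts * s).sum())  # zone conservation
    return {
        "SmallAreaEmphasis": float((P / s**2).sum()),
        "LargeAreaEmphasis": float((P * s**2).sum()),
        "GrayLevelNonUniformity": float((counts.sum(axis=1) ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((counts.sum(axis=1) ** 2).sum() / nz**2),
        "SizeZoneNonUniformity": float((counts.sum(axis=0) ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((counts.sum(axis=0) ** 2).sum() / nz**2),
        "ZonePercentage": float(nz / np_pixels),
        "GrayLevelVariance": float((pi * (np.arange(1, ng + 1) - mu_i) ** 2).sum()),
        "ZoneVariance": float((ps * (np.arange(1, ns + 1) - mu_s) ** 2).sum()),
        "ZoneEntropy": float(-(P * _log2(P)).sum()),
        "LowGrayLevelZoneEmphasis": float((P / i**2).sum()),
        "HighGrayLevelZoneEmphasis": float((P * i**2).sum()),
        "SmallAreaLowGrayLevelEmphasis": float((P / (i**2 * s**2)).sum()),
        "SmallAreaHighGrayLevelEmphasis": float((P * i**2 / s**2).sum()),
        "LargeAreaLowGrayLevelEmphasis": float((P * s**2 / i**2).sum()),
        "LargeAreaHighGrayLevelEmphasis": float((P * i**2 * s**2).sum()),
    }


# ---------------------------------------------------------------------------
# assembly

_FIRSTORDER = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
]
_GLCM = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumEntropy", "SumSquares",
]
_GLDM = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]
_GLRLM = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]

_GLSZM = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]

#: canonical ordered names of all 86 features, family-prefixed
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"firstorder_{n}" for n in _FIRSTORDER]
    + [f"glcm_{n}" for n in _GLCM]
    + [f"gldm_{n}" for n in _GLDM]
    + [f"glrlm_{n}" for n in _GLRLM]
    + [f"glszm_{n}" for n in _GLSZM]
)

FAMILY_COUNTS = {"firstorder": 18, "glcm": 22, "gldm": 14, "glrlm": 16, "glszm": 16}


def extract_features(
    image: RoiImage, config: ExtractionConfig | None = None
) -> dict[str, float]:
    """Compute all 86 features of one ROI on a shared discretization.

    Returns an ordered mapping keyed by the canonical family-prefixed
    names in :data:`FEATURE_NAMES`; deterministic given the config.
    """
    cfg = config or ExtractionConfig()
    q = discretize(image, cfg.n_bins)
    values: dict[str, float] = {}
    for name, val in first_order_features(image, q).items():
        values[f"firstorder_{name}"] = val
    for name, val in glcm_features(compute_glcm(q, cfg.angles)).items():
        values[f"glcm_{name}"] = val
    for name, val in gldm_features(compute_gldm(q, cfg.gldm_alpha)).items():
        values[f"gldm_{name}"] = val
    for name, val in glrlm_features(compute_glrlm(q, cfg.angles)).items():
        values[f"glrlm_{name}"] = val
    for name, val in glszm_features(compute_glszm(q, cfg.connectivity)).items():
        values[f"glszm_{name}"] = val
    out = {name: values[name] for name in FEATURE_NAMES}
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite features: {bad}")
    return out
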