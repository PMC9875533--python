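"""Perturbation-based feature-gene association across unpaired cohorts.

The imaging cohort (patients with radiomic feature values) and the
expression cohorts (patients with gene expression) contain different
people, so a feature and a gene can only be correlated after the two
cohorts are put in some correspondence.  A *perturbation study* draws an
equal-size subsample from each cohort within one HER2 class, pairs the
drawn samples, and computes a Pearson correlation for every
(feature, gene) pair; a pair is *flagged* when |r| exceeds a threshold
and the correlation p-value is below a threshold.  Repeating this many
times and requiring a minimum number of flags filters unstable pairings.
A gene is *positive-specific* for a feature when it is flagged at least
``min_hits`` times in the positive class and fewer than ``min_hits``
times in the negative class.

Pairing modes (see docs/methods.md for the reasoning):

* ``"shared"`` — one random index subset is drawn and applied to both
  cohorts.  Valid only when the two cohorts have the same number of
  samples in the class, i.e. when sample order encodes a latent
  correspondence (paired designs, or the bundled synthetic cohorts).
* ``"independent"`` — subsamples are drawn independently from each
  cohort and paired in drawn order.  This is the fully unpaired reading;
  under it any correlation is a pairing artifact, and the min-hits
  filter is the only guard.
* ``"auto"`` (default) — shared when class sizes coincide, otherwise
  independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import NEGATIVE, POSITIVE

__all__ = [
    "PerturbationConfig",
    "AssociationResult",
    "pearson_with_p",
    "run_perturbation",
    "identify_specific_genes",
]


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p-value (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PerturbationConfig:
    """Settings of the perturbation procedure.

    The published analysis used 75 perturbations with >= 6 hits on the
    test cohorts and 25 perturbations with >= 2 hits on the validation
    cohort; thresholds |r| > 0.3 and p < 0.05 in both.
    """

    n_perturbations: int = 75
    min_hits: int = 6
    r_threshold: float = 0.3
    p_threshold: float = 0.05
    subsample_size: int | str = "auto"  # "auto" = min(class sizes, 50)
    pairing: str = "auto"  # "auto" | "shared" | "independent"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.min_hits <= self.n_perturbations):
            raise ValueError("need 1 <= min_hits <= n_perturbations")
        if not (0 < self.r_threshold < 1):
            raise ValueError("need 0 < r_threshold < 1")
        if self.pairing not in ("auto", "shared", "independent"):
            raise ValueError(f"unknown pairing mode {self.pairing!r}")

    @classmethod
    def validation(cls, **kw) -> "PerturbationConfig":
        """The 25-perturbation / >=2-hit variant used on validation cohorts."""
        kw.setdefault("n_perturbations", 25)
        kw.setdefault("min_hits", 2)
        return cls(**kw)


@dataclass
class AssociationResult:
    """Accumulated evidence per (feature, gene) and the specific sets."""

    hit_counts_positive: pd.DataFrame  # features x genes, integer
    hit_counts_negative: pd.DataFrame
    mean_r_positive: pd.DataFrame  # mean r over positive-class perturbations
    positive_specific: dict[str, set[str]]  # feature -> genes
    config: PerturbationConfig

    def positive_related(self, min_hits: int | None = None) -> dict[str, set[str]]:
        return self._related(self.hit_counts_positive, min_hits)

    def negative_related(self, min_hits: int | None = None) -> dict[str, set[str]]:
        return self._related(self.hit_counts_negative, min_hits)

    def _related(self, hits: pd.DataFrame, min_hits: int | None) -> dict[str, set[str]]:
        mh = self.config.min_hits if min_hits is None else min_hits
        return {
            feat: set(hits.columns[hits.loc[feat] >= mh])
            for feat in hits.index
        }


def _rng_for(seed: int, class_idx: int, k: int) -> np.random.Generator:
    # independent, reproducible stream per (class, perturbation)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(class_idx, k))
    )


def _corr_matrix(F: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Pearson r between every feature column of F (m x p) and gene row of
    G (g x m).  Constant columns/rows yield r = 0 (never flagged)."""
    m = F.shape[0]
    Fz = F - F.mean(axis=0)
    sf = Fz.std(axis=0)
    Fz = np.where(sf > 0, Fz / np.where(sf > 0, sf, 1.0), 0.0)
    Gz = G - G.mean(axis=1, keepdims=True)
    sg = Gz.std(axis=1)
    Gz = np.where((sg > 0)[:, None], Gz / np.where(sg > 0, sg, 1.0)[:, None], 0.0)
    return (Fz.T @ Gz.T) / m


def _r_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return 2.0 * sps.t.sf(np.abs(t), df=n - 2)


def run_perturbation(
    features: pd.DataFrame,
    expr: pd.DataFrame,
    cfg: PerturbationConfig,
    k: int,
    class_label: str = POSITIVE,
    class_idx: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One perturbation study: subsample, pair, correlate, flag.

    Parameters
    ----------
    features
        Samples x features table restricted to the class (numeric columns
        only; max-normalized upstream).
    expr
        Genes x samples matrix restricted to the same class.
    cfg, k
        Configuration and the perturbation index; the draw is a pure
        function of (cfg.seed, class, k).

    Returns
    -------
    flags, r
        Boolean and float arrays of shape (n_features, n_genes).
    """
    n_img = len(features)
    n_expr = expr.shape[1]
    m = cfg.subsample_size
    if m == "auto":
        m = min(n_img, n_expr, 50)
    m = int(m)
    if m > n_img or m > n_expr:
        raise ValueError(
            f"subsample_size {m} exceeds a cohort ({n_img} imaging, {n_expr} expression)"
        )
    if m < 3:
        raise ValueError("subsample_size must be >= 3")
    pairing = cfg.pairing
    if pairing == "auto":
        pairing = "shared" if n_img == n_expr else "independent"
    if pairing == "shared" and n_img != n_expr:
        raise ValueError("shared pairing requires equal class sizes in both cohorts")
    rng = _rng_for(cfg.seed, class_idx if class_idx is not None else 0, k)
    if pairing == "shared":
        idx = rng.choice(n_img, size=m, replace=False)
        jdx = idx
    else:
        idx = rng.choice(n_img, size=m, replace=False)
        jdx = rng.choice(n_expr, size=m, replace=False)
    F = features.to_numpy(dtype=float)[idx]
    G = expr.to_numpy(dtype=float)[:, jdx]
    r = _corr_matrix(F, G)
    p = _r_pvalue(r, m)
    flags = (np.abs(r) > cfg.r_threshold) & (p < cfg.p_threshold)
    return flags, r


def identify_specific_genes(
    features: pd.DataFrame,
    expr_datasets: list[pd.DataFrame] | pd.DataFrame,
    expr_labels: list[pd.Series] | pd.Series,
    cfg: PerturbationConfig,
    label_col: str = "label",
) -> AssociationResult:
    """Run the full perturbation procedure on both HER2 classes.

    Parameters
    ----------
    features
        Patient-aggregated, max-normalized feature table with a
        ``label`` column.
    expr_datasets
        One or more genes x samples expression matrices (max-normalized
        per gene); perturbations are allocated round-robin across
        datasets and hit counts pooled over all of them.
    expr_labels
        Per-dataset sample labels ('positive'/'negative'), indexed by the
        matrix columns.

    Returns the per-(feature, gene) hit counts, the mean positive-class
    r, and the positive-specific gene set for every feature (positive
    related genes minus negative-related genes).
    """
    if isinstance(expr_datasets, pd.DataFrame):
        expr_datasets = [expr_datasets]
        expr_labels = [expr_labels]
    if len(expr_datasets) != len(expr_labels):
        raise ValueError("one label series per expression dataset required")
    feature_cols = [
        c for c in features.columns
        if c not in (label_col, "patient_id", "image_id")
    ]
    all_genes = sorted(set().union(*(set(d.index) for d in expr_datasets)))
    gene_pos = {g: i for i, g in enumerate(all_genes)}
    hits = {
        POSITIVE: np.zeros((len(feature_cols), len(all_genes)), dtype=np.int64),
        NEGATIVE: np.zeros((len(feature_cols), len(all_genes)), dtype=np.int64),
    }
    r_sum = np.zeros((len(feature_cols), len(all_genes)))
    r_n = np.zeros(len(all_genes), dtype=np.int64)
    for class_idx, class_label in enumerate((POSITIVE, NEGATIVE)):
        feat_class = features.loc[features[label_col] == class_label, feature_cols]
        for k in range(cfg.n_perturbations):
            d = k % len(expr_datasets)
            labels = expr_labels[d]
            expr_class = expr_datasets[d].loc[:, labels[labels == class_label].index]
            flags, r = run_perturbation(
                feat_class, expr_class, cfg, k, class_label, class_idx
            )
            cols = [gene_pos[g] for g in expr_datasets[d].index]
            hits[class_label][:, cols] += flags
            if class_label == POSITIVE:
                r_sum[:, cols] += r
                r_n[cols] += 1
    mean_r = r_sum / np.maximum(r_n, 1)[None, :]
    hp = pd.DataFrame(hits[POSITIVE], index=feature_cols, columns=all_genes)
    hn = pd.DataFrame(hits[NEGATIVE], index=feature_cols, columns=all_genes)
    mr = pd.DataFrame(mean_r, index=feature_cols, columns=all_genes)
    gene_arr = np.array(all_genes, dtype=object)
    specific = {}
    for i, feat in enumerate(feature_cols):
        mask = (hits[POSITIVE][i] >= cfg.min_hits) & (hits[NEGATIVE][i] < cfg.min_hits)
        specific[feat] = set(gene_arr[mask])
    return AssociationResult(
        hit_counts_positive=hp,
        hit_counts_negative=hn,
        mean_r_positive=mr,
        positive_specific=specific,
        config=cfg,
    )
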