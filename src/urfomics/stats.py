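"""Feature-table statistics: normalization, aggregation and differential selection.

Feature and gene values live on incommensurate scales, so both are put on
a common [0, 1]-ish scale by max-value normalization (each value divided
by its column maximum).  Images are averaged per patient before testing,
and HER2-differential features are selected by a two-sided Wilcoxon
rank-sum test combined with a fold-change screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DifferentialResult",
    "max_normalize",
    "aggregate_patients",
    "rank_sum_test",
    "select_differential",
]

POSITIVE, NEGATIVE = "positive", "negative"


def max_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each column by its maximum (maximum of absolute values when
    the column contains negatives, so the formula stays defined).

    All-zero columns are returned unchanged with a warning; all-NaN
    columns are an error.
    """
    matrix = matrix.astype(float)
    if matrix.isna().all(axis=0).any():
        bad = matrix.columns[matrix.isna().all(axis=0)].tolist()
        raise ValueError(f"all-NaN columns: {bad}")
    denom = matrix.abs().max(axis=0)
    zero = denom == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero column(s) left unnormalized",
            stacklevel=2,
        )
        denom = denom.mask(zero, 1.0)
    return matrix / denom


def aggregate_patients(
    table: pd.DataFrame,
    patient_col: str = "patient_id",
    label_col: str = "label",
) -> pd.DataFrame:
    """Average a per-image table to one row per patient.

    Every feature becomes the arithmetic mean over the patient's images.
    A patient whose images carry conflicting labels is a contract
    violation and raises.
    """
    if patient_col not in table.columns:
        raise ValueError(f"missing column {patient_col!r}")
    n_labels = table.groupby(patient_col)[label_col].nunique()
    if (n_labels > 1).any():
        bad = n_labels.index[n_labels > 1].tolist()
        raise ValueError(f"conflicting labels within patient(s): {bad}")
    feature_cols = [
        c for c in table.columns if c not in (patient_col, label_col, "image_id")
    ]
    out = table.groupby(patient_col, sort=True).agg(
        {**{c: "mean" for c in feature_cols}, label_col: "first"}
    )
    return out.reset_index()


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by enumeration when the combined sample size is at most 12 and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class DifferentialResult:
    feature: str
    p_value: float
    fold_change: float  # mean(positive) / mean(negative) on normalized values
    direction: str  # "up" if positives higher, else "down"
    selected: bool


def select_differential(
    table: pd.DataFrame,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.0,
    label_col: str = "label",
    adjust: bool = False,
) -> list[DifferentialResult]:
    """Select HER2-differential features by rank-sum p and fold change.

    Expects a max-normalized, patient-aggregated table with a binary
    ``label`` column.  A feature is selected when p < ``p_threshold`` and
    the direction-agnostic fold change max(FC, 1/FC) > ``fc_threshold``
    (most differential features decrease in positives, so a literal
    FC > 1 rule would discard them).  With ``adjust=True`` the p
    threshold is applied to Benjamini-Hochberg adjusted p-values instead.
    Results are sorted by p-value.
    """
    labels = table[label_col]
    if set(labels.unique()) - {POSITIVE, NEGATIVE}:
        raise ValueError(f"labels must be '{POSITIVE}'/'{NEGATIVE}'")
    pos = table[labels == POSITIVE]
    neg = table[labels == NEGATIVE]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >=2 samples per class")
    feature_cols = [
        c for c in table.columns
        if c not in (label_col, "patient_id", "image_id")
        and pd.api.types.is_numeric_dtype(table[c])
    ]
    rows = []
    for feat in feature_cols:
        p = rank_sum_test(pos[feat].to_numpy(), neg[feat].to_numpy())
        mu_pos = float(pos[feat].mean())
        mu_neg = float(neg[feat].mean())
        if mu_neg == 0:
            warnings.warn(f"zero negative-class mean for {feat}; FC=+inf",
                          stacklevel=2)
            fc = np.inf
        else:
            fc = mu_pos / mu_neg
        rows.append((feat, p, fc))
    pvals = np.array([r[1] for r in rows])
    p_eff = multipletests(pvals, method="fdr_bh")[1] if adjust else pvals
    results = []
    for (feat, p, fc), pe in zip(rows, p_eff):
        direction = "up" if fc > 1 else "down"
        fc_mag = max(fc, 1.0 / fc) if fc > 0 else np.inf
        selected = bool(pe < p_threshold and fc_mag > fc_threshold)
        results.append(DifferentialResult(feat, p, fc, direction, selected))
    return sorted(results, key=lambda r: r.p_value)
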