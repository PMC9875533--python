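"""HER2-status classifiers: native logistic regression, ROC/AUC and
repeated stratified holdout evaluation.

Logistic regression — the headline classifier — is implemented natively:
L2-penalized maximum likelihood by iteratively reweighted least squares
on train-standardized features, which makes the whole evaluation loop
deterministic given a seed.  Other learners (SVM, random forest, ...)
can be plugged in through the same fit/predict-probability interface.

AUC is the midrank Mann-Whitney statistic U/(n1*n0), identical to the
trapezoidal area under the empirical ROC curve; sensitivity/specificity
are reported at the Youden-optimal threshold of each test split.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Protocol

import numpy as np
from scipy import stats as sps

__all__ = [
    "LogisticModel",
    "SplitScheme",
    "EvalResult",
    "fit_logistic",
    "roc_auc",
    "youden_sensitivity_specificity",
    "stratified_split",
    "repeated_holdout",
    "compare_feature_sets",
]


class Classifier(Protocol):
    """Anything that fits on (X, y) and scores P(y=1)."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Classifier": ...
    def predict_proba1(self, X: np.ndarray) -> np.ndarray: ...


@dataclass
class LogisticModel:
    """L2-penalized logistic regression fit by IRLS.

    Features are standardized inside ``fit`` using training statistics
    only; the intercept is unpenalized.  ``l2`` is the ridge weight on
    the standardized scale (default 1.0).
    """

    l2: float = 1.0
    tol: float = 1e-8
    max_iter: int = 100
    weights: np.ndarray | None = None
    intercept: float = 0.0
    _mean: np.ndarray | None = None
    _std: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LogisticModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
        if y.sum() < 2 or (1 - y).sum() < 2:
            raise ValueError("need >=2 samples per class")
        if not np.isfinite(X).all():
            raise ValueError("non-finite features")
        self._mean = X.mean(axis=0)
        std = X.std(axis=0)
        self._std = np.where(std > 0, std, 1.0)
        Z = (X - self._mean) / self._std
        n, p = Z.shape
        A = np.hstack([np.ones((n, 1)), Z])
        beta = np.zeros(p + 1)
        pen = np.full(p + 1, self.l2)
        pen[0] = 0.0  # intercept unpenalized
        for _ in range(self.max_iter):
            eta = A @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            grad = A.T @ (y - mu) - pen * beta
            if np.linalg.norm(grad) < self.tol:
                break
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            H = (A * w[:, None]).T @ A + np.diag(pen)
            beta = beta + np.linalg.solve(H, grad)
        else:
            eta = A @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            grad = A.T @ (y - mu) - pen * beta
            if np.linalg.norm(grad) >= max(self.tol, 1e-6):
                raise RuntimeError(
                    f"IRLS did not converge in {self.max_iter} iterations "
                    f"(|grad| = {np.linalg.norm(grad):.3e}, l2 = {self.l2})"
                )
        self.intercept = float(beta[0])
        self.weights = beta[1:]
        return self

    def decision(self, X: np.ndarray) -> np.ndarray:
        if self.weights is None:
            raise RuntimeError("model not fitted")
        Z = (np.asarray(X, dtype=float) - self._mean) / self._std
        return self.intercept + Z @ self.weights

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision(X)))


def fit_logistic(X, y, l2: float = 1.0) -> LogisticModel:
    """Convenience wrapper: fit an L2 logistic model and return it."""
    return LogisticModel(l2=l2).fit(np.asarray(X), np.asarray(y))


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical ROC points and the midrank Mann-Whitney AUC.

    Returns (fpr, tpr, auc); fpr/tpr are stepwise points over the
    distinct score thresholds, auc = U/(n1*n0) with midranks, which
    equals the trapezoidal area under (fpr, tpr).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)  # midranks
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], sorted_labels.size - 1]
    tps = np.cumsum(sorted_labels)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    return fpr, tpr, float(auc)


def youden_sensitivity_specificity(scores, labels) -> tuple[float, float, float]:
    """(sensitivity, specificity, threshold) maximizing Youden's J."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    thresholds = np.unique(scores)
    best = (-np.inf, 0.0, 0.0, 0.0)
    pos = labels == 1
    for thr in thresholds:
        pred = scores >= thr
        sens = float((pred & pos).sum() / max(pos.sum(), 1))
        spec = float((~pred & ~pos).sum() / max((~pos).sum(), 1))
        j = sens + spec - 1.0
        if j > best[0]:
            best = (j, sens, spec, float(thr))
    return best[1], best[2], best[3]


@dataclass(frozen=True)
class SplitScheme:
    """Repeated stratified holdout: 70/30 by default."""

    train_fraction: float = 0.7
    n_repeats: int = 200
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")


def stratified_split(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator, stratified: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Index split with both classes guaranteed in train and test."""
    n = y.size
    for _ in range(10):
        if stratified:
            train_idx = []
            for cls in np.unique(y):
                idx = np.nonzero(y == cls)[0]
                idx = rng.permutation(idx)
                k = max(1, int(round(train_fraction * idx.size)))
                k = min(k, idx.size - 1)
                train_idx.append(idx[:k])
            train = np.sort(np.concatenate(train_idx))
        else:
            perm = rng.permutation(n)
            train = np.sort(perm[: int(round(train_fraction * n))])
        test = np.setdiff1d(np.arange(n), train)
        if np.unique(y[train]).size == 2 and np.unique(y[test]).size == 2:
            return train, test
    raise ValueError("could not produce a split containing both classes")


@dataclass
class EvalResult:
    classifier: str
    feature_set: str
    aucs: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def mean_sensitivity(self) -> float:
        return float(self.sensitivities.mean())

    @property
    def mean_specificity(self) -> float:
        return float(self.specificities.mean())


def repeated_holdout(
    X,
    y,
    model_factory=None,
    scheme: SplitScheme | None = None,
    feature_set: str = "differential",
) -> EvalResult:
    """Repeated stratified 70/30 evaluation of one classifier.

    ``model_factory`` returns a fresh classifier per repeat (default: L2
    logistic regression).  Deterministic given ``scheme.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    scheme = scheme or SplitScheme()
    factory = model_factory or (lambda: LogisticModel())
    # stable across processes (unlike hash()) so runs are reproducible
    set_key = zlib.crc32(feature_set.encode()) % 2**31
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(scheme.seed), spawn_key=(set_key,))
    )
    aucs, sens, spec = [], [], []
    for _ in range(scheme.n_repeats):
        train, test = stratified_split(y, scheme.train_fraction, rng, scheme.stratified)
        model = factory().fit(X[train], y[train])
        scores = model.predict_proba1(X[test])
        _, _, auc = roc_auc(scores, y[test])
        s, sp, _ = youden_sensitivity_specificity(scores, y[test])
        aucs.append(auc)
        sens.append(s)
        spec.append(sp)
    name = type(factory()).__name__
    return EvalResult(
        classifier=name,
        feature_set=feature_set,
        aucs=np.array(aucs),
        sensitivities=np.array(sens),
        specificities=np.array(spec),
    )


def compare_feature_sets(
    X_diff,
    X_module,
    y,
    model_factory=None,
    scheme: SplitScheme | None = None,
) -> dict:
    """Evaluate two feature sets on identical splits; report per-repeat ΔAUC.

    ΔAUC = AUC(module) − AUC(differential) per repeat.
    """
    X_diff = np.asarray(X_diff, dtype=float)
    X_module = np.asarray(X_module, dtype=float)
    y = np.asarray(y).astype(int)
    if X_diff.shape[0] != X_module.shape[0] or X_diff.shape[0] != y.size:
        raise ValueError("feature tables must cover the same samples")
    scheme = scheme or SplitScheme()
    factory = model_factory or (lambda: LogisticModel())
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(scheme.seed)))
    rows = {"differential": [], "module": []}
    for _ in range(scheme.n_repeats):
        train, test = stratified_split(y, scheme.train_fraction, rng, scheme.stratified)
        for name, X in (("differential", X_diff), ("module", X_module)):
            model = factory().fit(X[train], y[train])
            _, _, auc = roc_auc(model.predict_proba1(X[test]), y[test])
            rows[name].append(auc)
    diff = np.array(rows["differential"])
    mod = np.array(rows["module"])
    return {
        "auc_differential": diff,
        "auc_module": mod,
        "delta_auc": mod - diff,
        "mean_delta_auc": float((mod - diff).mean()),
        "mean_auc_differential": float(diff.mean()),
        "mean_auc_module": float(mod.mean()),
    }
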