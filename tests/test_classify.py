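"""Logistic regression, ROC/AUC and repeated-holdout evaluation."""

import numpy as np
import pytest
from scipy import optimize, special, stats as sps

from urfomics.classify import (
    LogisticModel,
    SplitScheme,
    compare_feature_sets,
    fit_logistic,
    repeated_holdout,
    roc_auc,
    stratified_split,
    youden_sensitivity_specificity,
)


def penalized_loss(beta, A, y, pen):
    eta = A @ beta
    return -(y * eta - np.logaddexp(0, eta)).sum() + 0.5 * (pen * beta**2).sum()


class TestLogistic:
    def test_symmetric_separable_case(self):
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        m = fit_logistic(X, y, l2=0.1)
        assert m.weights[0] > 0
        assert m.intercept == pytest.approx(0.0, abs=1e-6)

    def test_loss_matches_bruteforce_optimizer(self, rng):
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] + 0.5 * rng.normal(size=40) > 0).astype(int)
        m = fit_logistic(X, y, l2=1.0)
        Z = (X - X.mean(0)) / X.std(0)
        A = np.hstack([np.ones((40, 1)), Z])
        pen = np.array([0.0, 1.0, 1.0, 1.0])
        beta_hat = np.concatenate([[m.intercept], m.weights])
        res = optimize.minimize(
            penalized_loss, np.zeros(4), args=(A, y, pen), method="BFGS",
            options={"gtol": 1e-10, "maxiter": 1000},
        )
        assert penalized_loss(beta_hat, A, y, pen) == pytest.approx(res.fun, abs=1e-6)

    def test_matches_sklearn_predictions(self, rng):
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        X = rng.normal(size=(80, 4))
        y = (X @ np.array([1.0, -0.5, 0, 0.3]) + rng.normal(size=80) > 0).astype(int)
        Z = (X - X.mean(0)) / X.std(0)
        ours = fit_logistic(X, y, l2=1.0)
        ref = sklearn_lm.LogisticRegression(C=1.0).fit(Z, y)
        np.testing.assert_allclose(ours.weights, ref.coef_[0], atol=5e-3)

    def test_duplicated_feature_weights_split_symmetrically(self, rng):
        # penalized-likelihood symmetry: duplicate columns receive exactly
        # equal weights (the effective ridge on that direction halves, so
        # predictions shift slightly but stay close)
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] > 0).astype(int)
        m1 = fit_logistic(X, y, l2=1.0)
        m2 = fit_logistic(np.hstack([X, X[:, :1]]), y, l2=1.0)
        assert m2.weights[0] == pytest.approx(m2.weights[2], abs=1e-9)
        p1 = m1.predict_proba1(X)
        p2 = m2.predict_proba1(np.hstack([X, X[:, :1]]))
        assert np.abs(p1 - p2).max() < 0.1

    def test_null_features_give_chance_auc(self, rng):
        n = 500
        X = rng.normal(size=(n, 5))
        y = rng.integers(0, 2, n)
        m = fit_logistic(X[: n // 2], y[: n // 2], l2=1.0)
        _, _, auc = roc_auc(m.predict_proba1(X[n // 2 :]), y[n // 2 :])
        assert abs(auc - 0.5) < 0.08

    def test_unbalanced_or_tiny_classes_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones((4, 1)), np.array([1, 1, 1, 0]))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])[2] == 1.0

    def test_three_of_four_concordant_pairs(self):
        assert roc_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])[2] == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])[2] == pytest.approx(0.5)

    def test_equals_trapezoid_area_and_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            scores = rng.normal(size=40)
            labels = rng.integers(0, 2, 40)
            if labels.sum() in (0, 40):
                continue
            fpr, tpr, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)
            assert auc == pytest.approx(sk.roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform_and_flips_on_negation(self, rng):
        scores = rng.normal(size=30)
        labels = (rng.random(30) < 0.4).astype(int)
        base = roc_auc(scores, labels)[2]
        assert roc_auc(np.exp(2 * scores), labels)[2] == pytest.approx(base)
        assert roc_auc(-scores, labels)[2] == pytest.approx(1 - base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_youden_on_separable_scores(self):
        sens, spec, thr = youden_sensitivity_specificity(
            [0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]
        )
        assert sens == 1.0 and spec == 1.0


class TestRepeatedHoldout:
    def test_mean_auc_matches_gaussian_closed_form(self):
        # two-Gaussian scores: analytic AUC = Phi(d'/sqrt(2))
        rng = np.random.default_rng(100)
        d_prime = 1.0
        n = 600
        X = np.concatenate([
            rng.normal(0, 1, n // 2), rng.normal(d_prime, 1, n // 2)
        ]).reshape(-1, 1)
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        res = repeated_holdout(X, y, scheme=SplitScheme(n_repeats=200, seed=8))
        expected = sps.norm.cdf(d_prime / np.sqrt(2))
        assert abs(res.mean_auc - expected) < 0.03

    def test_label_shuffled_data_near_chance(self):
        rng = np.random.default_rng(200)
        X = rng.normal(size=(400, 4))
        y = rng.permutation([0] * 200 + [1] * 200)
        res = repeated_holdout(X, y, scheme=SplitScheme(n_repeats=200, seed=9))
        assert 0.45 <= res.mean_auc <= 0.55

    def test_same_seed_gives_identical_auc_vectors(self, rng):
        X = rng.normal(size=(80, 3))
        y = np.array([0, 1] * 40)
        s = SplitScheme(n_repeats=20, seed=4)
        r1 = repeated_holdout(X, y, scheme=s)
        r2 = repeated_holdout(X, y, scheme=s)
        np.testing.assert_array_equal(r1.aucs, r2.aucs)

    def test_stratified_split_preserves_both_classes(self, rng):
        y = np.array([0] * 90 + [1] * 10)
        for _ in range(50):
            train, test = stratified_split(y, 0.7, rng)
            assert set(y[train]) == {0, 1} and set(y[test]) == {0, 1}
            assert len(np.intersect1d(train, test)) == 0


class TestCompareFeatureSets:
    def test_identical_sets_give_zero_delta(self, rng):
        X = rng.normal(size=(100, 3))
        y = np.array([0, 1] * 50)
        out = compare_feature_sets(X, X, y, scheme=SplitScheme(n_repeats=20, seed=2))
        np.testing.assert_array_equal(out["delta_auc"], np.zeros(20))

    def test_pure_noise_additions_do_not_hurt_much(self):
        rng = np.random.default_rng(33)
        n = 300
        signal = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(1.5, 1, n // 2)])
        X_diff = signal.reshape(-1, 1)
        X_module = np.hstack([X_diff, rng.normal(size=(n, 4))])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        out = compare_feature_sets(X_diff, X_module, y,
                                   scheme=SplitScheme(n_repeats=100, seed=3))
        assert out["mean_delta_auc"] >= -0.02

    def test_informative_additions_help(self):
        rng = np.random.default_rng(44)
        n = 300
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        weak = (0.4 * y + rng.normal(size=n)).reshape(-1, 1)
        strong = (1.2 * y + rng.normal(size=n)).reshape(-1, 1)
        out = compare_feature_sets(weak, np.hstack([weak, strong]), y,
                                   scheme=SplitScheme(n_repeats=100, seed=5))
        assert out["mean_delta_auc"] > 0

    def test_sample_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="same samples"):
            compare_feature_sets(
                rng.normal(size=(10, 2)), rng.normal(size=(12, 2)),
                np.array([0, 1] * 5),
            )
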