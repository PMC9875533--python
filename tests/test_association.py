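"""Pearson correlation and the perturbation association procedure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from urfomics.association import (
    PerturbationConfig,
    _corr_matrix,
    _r_pvalue,
    identify_specific_genes,
    pearson_with_p,
    run_perturbation,
)


class TestPearson:
    def test_self_correlation_is_one(self):
        r, p = pearson_with_p([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert r == pytest.approx(1.0)

    def test_hand_computed_example(self):
        r, _ = pearson_with_p([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(3 / np.sqrt(28 / 3))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_null_p_values_uniform(self, rng):
        ps = []
        for _ in range(2000):
            x, y = rng.normal(size=50), rng.normal(size=50)
            ps.append(pearson_with_p(x, y)[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_vectorized_matches_scipy(self, rng):
        F = rng.normal(size=(30, 4))
        G = rng.normal(size=(6, 30))
        R = _corr_matrix(F, G)
        P = _r_pvalue(R, 30)
        for i in range(4):
            for j in range(6):
                r, p = sps.pearsonr(F[:, i], G[j])
                assert R[i, j] == pytest.approx(r, abs=1e-12)
                assert P[i, j] == pytest.approx(p, rel=1e-6)


def make_cohorts(rng, n=100, n_genes=40, planted_r=0.9):
    """Feature table and expression with gene G0000 = planted copy of 'f'
    in positives (latent positional alignment), noise elsewhere."""
    f_pos = rng.normal(10, 2, n)
    f_neg = rng.normal(10, 2, n)
    features = pd.DataFrame({
        "f": np.concatenate([f_pos, f_neg]),
        "g2": rng.normal(5, 1, 2 * n),
        "label": ["positive"] * n + ["negative"] * n,
    })
    genes = [f"G{i:04d}" for i in range(n_genes)]
    X = rng.normal(size=(n_genes, 2 * n))
    z = (f_pos - f_pos.mean()) / f_pos.std()
    X[0, :n] = planted_r * z + np.sqrt(1 - planted_r**2) * rng.normal(size=n)
    expr = pd.DataFrame(
        X, index=genes,
        columns=[f"S{i}" for i in range(2 * n)],
    )
    labels = pd.Series(["positive"] * n + ["negative"] * n, index=expr.columns)
    return features, expr, labels


class TestRunPerturbation:
    def test_planted_identity_gene_flagged_with_r_one(self, rng):
        features, expr, labels = make_cohorts(rng)
        pos = features[features.label == "positive"][["f", "g2"]]
        expr_pos = expr.loc[:, labels == "positive"].copy()
        # make G0001 an exact copy of the feature under shared pairing
        expr_pos.iloc[1] = pos["f"].to_numpy()
        cfg = PerturbationConfig(pairing="shared", seed=3)
        flags, r = run_perturbation(pos, expr_pos, cfg, k=0)
        assert flags[0, 1]
        assert r[0, 1] == pytest.approx(1.0)

    def test_deterministic_given_seed_and_index(self, rng):
        features, expr, labels = make_cohorts(rng)
        pos = features[features.label == "positive"][["f", "g2"]]
        expr_pos = expr.loc[:, labels == "positive"]
        cfg = PerturbationConfig(seed=9)
        f1, r1 = run_perturbation(pos, expr_pos, cfg, k=4)
        f2, r2 = run_perturbation(pos, expr_pos, cfg, k=4)
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(r1, r2)
        f3, _ = run_perturbation(pos, expr_pos, cfg, k=5)
        assert not np.array_equal(f1, f3)

    def test_null_flag_rate_matches_nominal_within_3_sigma(self, rng):
        # one perturbation over many independent null genes: flag count is
        # Binomial(n_genes, p0) with p0 = P(|r| > max(0.3, r crit at 0.05))
        n, n_genes, m = 200, 2000, 40
        features = pd.DataFrame({
            "f": rng.normal(size=n), "label": ["positive"] * n
        })
        expr = pd.DataFrame(rng.normal(size=(n_genes, n)),
                            index=[f"G{i}" for i in range(n_genes)],
                            columns=[f"S{i}" for i in range(n)])
        cfg = PerturbationConfig(subsample_size=m, pairing="independent", seed=1)
        flags, _ = run_perturbation(features[["f"]], expr, cfg, k=0)
        t_crit = sps.t.ppf(0.975, m - 2)
        r_crit = max(0.3, t_crit / np.sqrt(m - 2 + t_crit**2))
        t_at = r_crit * np.sqrt((m - 2) / (1 - r_crit**2))
        p0 = 2 * sps.t.sf(t_at, m - 2)
        sigma = np.sqrt(n_genes * p0 * (1 - p0))
        assert abs(flags.sum() - n_genes * p0) < 3 * sigma

    def test_oversized_subsample_rejected(self, rng):
        features, expr, labels = make_cohorts(rng, n=20)
        pos = features[features.label == "positive"][["f", "g2"]]
        cfg = PerturbationConfig(subsample_size=30)
        with pytest.raises(ValueError, match="subsample_size"):
            run_perturbation(pos, expr.loc[:, labels == "positive"], cfg, k=0)


class TestIdentifySpecificGenes:
    def test_planted_gene_is_positive_specific(self, rng):
        features, expr, labels = make_cohorts(rng, n=100, planted_r=0.9)
        cfg = PerturbationConfig(seed=11)
        res = identify_specific_genes(features, expr, labels, cfg)
        assert "G0000" in res.positive_specific["f"]

    def test_gene_correlated_in_both_classes_excluded(self, rng):
        features, expr, labels = make_cohorts(rng, n=100)
        # plant the same association in the negative class too
        f_neg = features.loc[features.label == "negative", "f"].to_numpy()
        z = (f_neg - f_neg.mean()) / f_neg.std()
        expr.iloc[0, 100:] = 0.9 * z + np.sqrt(1 - 0.81) * rng.normal(size=100)
        cfg = PerturbationConfig(seed=11)
        res = identify_specific_genes(features, expr, labels, cfg)
        assert "G0000" not in res.positive_specific["f"]
        assert "G0000" in res.positive_related()["f"]

    def test_min_hits_monotonicity(self, rng):
        # raising min_hits can only shrink the related sets
        features, expr, labels = make_cohorts(rng, n=60)
        cfg = PerturbationConfig(n_perturbations=20, min_hits=2, seed=5)
        res = identify_specific_genes(features, expr, labels, cfg)
        previous = None
        for mh in (2, 3, 5, 10):
            related = res.positive_related(mh)
            if previous is not None:
                for f in related:
                    assert related[f] <= previous[f]
            previous = related

    def test_exclusion_invariant(self, rng):
        features, expr, labels = make_cohorts(rng, n=60)
        cfg = PerturbationConfig(n_perturbations=20, min_hits=2, seed=6)
        res = identify_specific_genes(features, expr, labels, cfg)
        neg = res.negative_related()
        for f, genes in res.positive_specific.items():
            assert not genes & neg[f]

    def test_whole_procedure_reproducible(self, rng):
        features, expr, labels = make_cohorts(rng, n=60)
        cfg = PerturbationConfig(n_perturbations=10, min_hits=2, seed=7)
        r1 = identify_specific_genes(features, expr, labels, cfg)
        r2 = identify_specific_genes(features, expr, labels, cfg)
        assert r1.positive_specific == r2.positive_specific
        pd.testing.assert_frame_equal(r1.hit_counts_positive, r2.hit_counts_positive)

    def test_validation_variant_configuration(self):
        cfg = PerturbationConfig.validation(seed=1)
        assert cfg.n_perturbations == 25 and cfg.min_hits == 2
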