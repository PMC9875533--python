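"""The synthetic study generator: determinism and planted structure."""

import numpy as np
import pandas as pd
import pytest

from urfomics.enrichment import read_gmt
from urfomics.images import load_roi_image
from urfomics.stats import aggregate_patients, max_normalize, rank_sum_test
from urfomics.synthetic import (
    CatalogSpec,
    ExpressionSpec,
    PhantomSpec,
    PLANTED_DIFFERENTIAL,
    generate_catalog,
    generate_expression,
    generate_phantoms,
    simulate,
)
from urfomics.texture import extract_features


SMALL = PhantomSpec(image_size=(48, 48), ellipse_radii=(16.0, 12.0), images_per_patient=1)


def feature_table(images, manifest, feats=("glszm_ZoneEntropy",)):
    rows = []
    for img, (_, m) in zip(images, manifest.iterrows()):
        full = extract_features(img)
        rows.append({"patient_id": m.patient_id, "label": m.label,
                     **{f: full[f] for f in feats}})
    return pd.DataFrame(rows)


class TestPhantoms:
    def test_deterministic_given_seed(self):
        i1, m1 = generate_phantoms(3, SMALL, seed=5)
        i2, m2 = generate_phantoms(3, SMALL, seed=5)
        pd.testing.assert_frame_equal(m1, m2)
        for a, b in zip(i1, i2):
            np.testing.assert_array_equal(a.pixels, b.pixels)
            np.testing.assert_array_equal(a.mask, b.mask)

    def test_zone_entropy_separates_classes_and_is_higher_in_positives(self):
        images, manifest = generate_phantoms(25, SMALL, seed=2)
        t = feature_table(images, manifest)
        pos = t[t.label == "positive"]["glszm_ZoneEntropy"]
        neg = t[t.label == "negative"]["glszm_ZoneEntropy"]
        assert rank_sum_test(pos, neg) < 0.05
        assert pos.mean() > neg.mean()

    def test_null_spec_gives_no_class_effect(self):
        spec = PhantomSpec(image_size=(48, 48), ellipse_radii=(16.0, 12.0),
                           images_per_patient=1,
                           smoothing_positive=1.2, smoothing_negative=1.2)
        images, manifest = generate_phantoms(25, spec, seed=3)
        t = feature_table(images, manifest)
        p = rank_sum_test(
            t[t.label == "positive"]["glszm_ZoneEntropy"],
            t[t.label == "negative"]["glszm_ZoneEntropy"],
        )
        assert p > 0.05

    def test_written_pngs_round_trip(self, tmp_path):
        images, manifest = generate_phantoms(2, SMALL, seed=7, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        first = manifest.iloc[0]
        roi = load_roi_image(
            tmp_path / "images" / f"{first.image_id}.png",
            tmp_path / "masks" / f"{first.image_id}.png",
        )
        np.testing.assert_array_equal(roi.pixels, images[0].pixels)
        np.testing.assert_array_equal(roi.mask, images[0].mask)


def toy_patient_table(rng, n=40, n_feats=12):
    cols = {f"feat{j:02d}": rng.uniform(1, 2, 2 * n) for j in range(n_feats)}
    cols["feat00"] = np.concatenate([rng.normal(3, 0.3, n), rng.normal(2, 0.3, n)])
    t = pd.DataFrame(cols)
    t["label"] = ["positive"] * n + ["negative"] * n
    t["patient_id"] = [f"p{i}" for i in range(2 * n)]
    return t


class TestExpression:
    SPEC = ExpressionSpec(n_genes=200, genes_per_feature=10, n_datasets=2,
                          n_aux_twins=1, planted_features=("feat00",))

    def test_planted_pairs_reach_target_correlation_under_alignment(self, rng):
        table = toy_patient_table(rng)
        datasets, labels, truth = generate_expression(table, self.SPEC, seed=4)
        expr, lab = datasets[0], labels[0]
        pos_profile = table[table.label == "positive"]["feat00"].to_numpy()
        rs = []
        for g in truth["planted_genes"]["feat00"]:
            gv = expr.loc[g, lab == "positive"].to_numpy()
            rs.append(np.corrcoef(pos_profile, gv)[0, 1])
        assert np.mean(np.abs(rs)) > 0.75  # r* = 0.85 up to sampling noise

    def test_planted_genes_null_in_negative_class(self, rng):
        table = toy_patient_table(rng)
        datasets, labels, truth = generate_expression(table, self.SPEC, seed=4)
        expr, lab = datasets[0], labels[0]
        neg_profile = table[table.label == "negative"]["feat00"].to_numpy()
        rs = [
            np.corrcoef(neg_profile, expr.loc[g, lab == "negative"])[0, 1]
            for g in truth["planted_genes"]["feat00"]
        ]
        assert np.mean(np.abs(rs)) < 0.3

    def test_twin_chosen_among_non_differential_features(self, rng):
        table = toy_patient_table(rng)
        _, _, truth = generate_expression(table, self.SPEC, seed=4)
        assert truth["aux_twins"]
        for aux in truth["aux_twins"]:
            assert aux != "feat00"  # the only differential feature

    def test_deterministic(self, rng):
        table = toy_patient_table(rng)
        d1, _, t1 = generate_expression(table, self.SPEC, seed=9)
        d2, _, t2 = generate_expression(table, self.SPEC, seed=9)
        pd.testing.assert_frame_equal(d1[0], d2[0])
        assert t1 == t2


class TestCatalog:
    def test_planted_terms_cover_planted_genes(self, rng):
        table = toy_patient_table(rng)
        spec = ExpressionSpec(n_genes=300, genes_per_feature=30, n_datasets=1,
                              n_aux_twins=0, planted_features=("feat00",))
        datasets, _, truth = generate_expression(table, spec, seed=1)
        catalog, cat_truth = generate_catalog(list(datasets[0].index), truth, seed=1)
        planted = set(truth["planted_genes"]["feat00"])
        for term in cat_truth["planted_terms"]["feat00"]:
            members = catalog.terms[term]
            assert members <= planted
            assert len(members) == CatalogSpec().genes_per_term

    def test_universe_is_exactly_the_gene_pool(self, rng):
        table = toy_patient_table(rng)
        spec = ExpressionSpec(n_genes=300, genes_per_feature=10, n_datasets=1,
                              n_aux_twins=0, planted_features=("feat00",))
        datasets, _, truth = generate_expression(table, spec, seed=1)
        catalog, _ = generate_catalog(
            list(datasets[0].index), truth, seed=1,
            spec=CatalogSpec(terms_per_feature=3, genes_per_term=6, n_decoy_terms=5),
        )
        assert catalog.universe == frozenset(datasets[0].index)


class TestSimulate:
    def test_writes_complete_study_and_gmt_round_trips(self, tmp_path):
        truth = simulate(
            tmp_path, seed=1, n_patients_per_class=6,
            phantom_spec=SMALL,
            expression_spec=ExpressionSpec(n_genes=150, genes_per_feature=5,
                                           n_datasets=2, n_aux_twins=1),
            catalog_spec=CatalogSpec(terms_per_feature=2, genes_per_term=4,
                                     n_decoy_terms=5),
        )
        for name in ("manifest.csv", "features.csv", "expr_0.tsv", "expr_1.tsv",
                     "expr_labels_0.csv", "catalog.gmt", "truth.json"):
            assert (tmp_path / name).exists(), name
        catalog = read_gmt(tmp_path / "catalog.gmt")
        expr = pd.read_csv(tmp_path / "expr_0.tsv", sep="\t", index_col=0)
        assert catalog.universe == frozenset(expr.index)
        assert set(truth["planted_differential"]) == set(PLANTED_DIFFERENTIAL)
        feats = pd.read_csv(tmp_path / "features.csv")
        assert feats.shape[1] == 86 + 3
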