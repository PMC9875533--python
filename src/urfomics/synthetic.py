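"""Synthetic study generator: texture phantoms, expression matrices with
planted feature-gene structure, and gene-set catalogs with planted terms.

Every pipeline stage is testable without any external download:

* **Phantoms** emulate ROI-masked ultrasound B-mode texture as
  Gaussian-smoothed Gamma speckle inside an elliptical ROI.  The two
  HER2 classes differ only in the smoothing scale; the positive class
  uses the larger scale, which spreads zone sizes and gray levels over
  a wider range and raises Zone Entropy — the direction reported for
  HER2-positive tumours — while shifting the other zone/run-size
  statistics.
* **Expression cohorts** contain different (nominal) patients from the
  imaging cohort but are latently index-aligned to it: within each
  class, sample t's planted genes follow g = r*·z(f_t) + sqrt(1-r*²)·ε
  where z(f_t) is the standardized profile of the planted feature over
  the imaging patients of that class.  Planted genes are pure noise in
  the other class; null genes are noise everywhere.
* **Catalogs** plant terms drawn from the planted gene lists (shared
  between a differential feature and its auxiliary "function twin") on
  top of uniform decoy terms.

Ground truth (planted differential features, gene lists, terms, twins)
is always written/returned beside the data so recovery can be scored
without re-deriving it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .enrichment import GeneSetCollection, write_gmt
from .images import RoiImage
from .stats import NEGATIVE, POSITIVE, aggregate_patients, max_normalize, select_differential
from .texture import ExtractionConfig, extract_features

__all__ = [
    "PhantomSpec",
    "ExpressionSpec",
    "CatalogSpec",
    "PLANTED_DIFFERENTIAL",
    "generate_phantoms",
    "generate_expression",
    "generate_catalog",
    "simulate",
]

#: the eight zone/run-statistic features the generator is designed to
#: separate between classes (the differential set reported for HER2)
PLANTED_DIFFERENTIAL: tuple[str, ...] = (
    "glszm_SizeZoneNonUniformityNormalized",
    "glszm_ZoneEntropy",
    "glrlm_ShortRunHighGrayLevelEmphasis",
    "glszm_SizeZoneNonUniformity",
    "glszm_SmallAreaEmphasis",
    "glrlm_ShortRunEmphasis",
    "glrlm_RunLengthNonUniformityNormalized",
    "glszm_SmallAreaHighGrayLevelEmphasis",
)


@dataclass(frozen=True)
class PhantomSpec:
    """Two-class speckle phantom parameters.

    The smoothing scale controls texture heterogeneity: larger scales
    produce coarser speckle whose zone sizes and gray levels spread over
    a wider range, which raises Zone Entropy (for this phantom family ZE
    grows monotonically with the smoothing scale under fixed-bin-count
    discretization).  The positive class therefore defaults to the
    larger scale, reproducing the reported direction of higher ZE in
    HER2-positive tumours.  Setting the two scales equal yields a null
    phantom with no class difference.
    """

    image_size: tuple[int, int] = (64, 64)
    gamma_shape: float = 2.0
    gamma_scale: float = 1.0
    smoothing_positive: float = 1.6
    smoothing_negative: float = 0.8
    images_per_patient: int = 2
    ellipse_radii: tuple[float, float] = (22.0, 16.0)
    radii_jitter: float = 3.0


def _phantom_image(rng: np.random.Generator, spec: PhantomSpec, sigma: float) -> RoiImage:
    h, w = spec.image_size
    speckle = rng.gamma(spec.gamma_shape, spec.gamma_scale, size=(h, w))
    img = ndimage.gaussian_filter(speckle, sigma=sigma)
    lo, hi = img.min(), img.max()
    img8 = np.round((img - lo) / max(hi - lo, 1e-12) * 255.0).astype(np.uint8)
    ra = spec.ellipse_radii[0] + rng.uniform(-spec.radii_jitter, spec.radii_jitter)
    rb = spec.ellipse_radii[1] + rng.uniform(-spec.radii_jitter, spec.radii_jitter)
    cy = h / 2 + rng.uniform(-2, 2)
    cx = w / 2 + rng.uniform(-2, 2)
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((yy - cy) / rb) ** 2 + ((xx - cx) / ra) ** 2 <= 1.0
    return RoiImage(pixels=img8.astype(float), mask=mask)


def generate_phantoms(
    n_patients_per_class: int = 60,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    out_dir: Path | str | None = None,
) -> tuple[list[RoiImage], pd.DataFrame]:
    """Generate phantom image/mask pairs and a manifest.

    Returns the in-memory images and a manifest DataFrame with columns
    (image_id, patient_id, label); deterministic per seed.  When
    ``out_dir`` is given, 8-bit PNGs are written to ``images/`` and
    ``masks/`` plus ``manifest.csv``.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(0,)))
    images: list[RoiImage] = []
    rows = []
    for label, sigma, prefix in (
        (POSITIVE, spec.smoothing_positive, "P"),
        (NEGATIVE, spec.smoothing_negative, "N"),
    ):
        for i in range(n_patients_per_class):
            patient = f"{prefix}{i:03d}"
            for j in range(spec.images_per_patient):
                img = _phantom_image(rng, spec, sigma)
                image_id = f"{patient}_img{j}"
                images.append(
                    RoiImage(
                        pixels=img.pixels,
                        mask=img.mask,
                        image_id=image_id,
                        patient_id=patient,
                    )
                )
                rows.append({"image_id": image_id, "patient_id": patient, "label": label})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
        for img in images:
            iio.imwrite(out_dir / "images" / f"{img.image_id}.png",
                        img.pixels.astype(np.uint8))
            iio.imwrite(out_dir / "masks" / f"{img.image_id}.png",
                        (img.mask * 255).astype(np.uint8))
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return images, manifest


@dataclass(frozen=True)
class ExpressionSpec:
    """Planted feature-gene structure of the synthetic expression cohorts.

    ``r_target`` is the Pearson correlation a planted (feature, gene)
    pair attains in the positive class under the latent alignment;
    the generator mixes the standardized feature profile and unit
    Gaussian noise as r*·z + sqrt(1-r*²)·ε.
    """

    n_genes: int = 1000
    genes_per_feature: int = 30
    r_target: float = 0.85
    n_datasets: int = 3
    n_aux_twins: int = 2
    baseline: float = 8.0
    planted_features: tuple[str, ...] = PLANTED_DIFFERENTIAL


def _choose_twins(
    table: pd.DataFrame, spec: ExpressionSpec, label_col: str = "label"
) -> dict[str, str]:
    """Pick non-differential "function twin" features for the first
    planted features, using the same selection procedure the pipeline
    applies, so twins are guaranteed non-differential on this table."""
    results = select_differential(table, label_col=label_col)
    selected = {r.feature for r in results if r.selected}
    pos = table[table[label_col] == POSITIVE]
    candidates = [
        r.feature
        for r in sorted(results, key=lambda r: -r.p_value)
        if r.feature not in selected
        and np.isfinite(pos[r.feature]).all()
        and pos[r.feature].std() > 0
    ]
    twins = {}
    for aux, partner in zip(candidates[: spec.n_aux_twins], spec.planted_features):
        twins[aux] = partner
    return twins


def generate_expression(
    feature_table: pd.DataFrame,
    spec: ExpressionSpec | None = None,
    seed: int = 0,
    label_col: str = "label",
) -> tuple[list[pd.DataFrame], list[pd.Series], dict]:
    """Generate expression cohorts latently aligned to the imaging cohort.

    Parameters
    ----------
    feature_table
        Patient-aggregated feature table with a label column; the
        positive/negative row order defines the latent correspondence of
        the expression samples (positionally, within each class).

    Returns (datasets, labels, truth): one genes x samples DataFrame and
    label Series per dataset, and a truth record listing planted
    (feature -> genes), the auxiliary twin map and r_target.
    """
    spec = spec or ExpressionSpec()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(1,)))
    twins = _choose_twins(feature_table, spec, label_col)
    planted_all = list(spec.planted_features) + list(twins.keys())
    missing = [f for f in planted_all if f not in feature_table.columns]
    if missing:
        raise ValueError(f"planted features absent from table: {missing}")
    n_planted = len(planted_all) * spec.genes_per_feature
    if n_planted >= spec.n_genes:
        raise ValueError("n_genes too small for the planted lists")
    gene_names = [f"G{i:04d}" for i in range(spec.n_genes)]
    planted_genes: dict[str, list[str]] = {}
    cursor = 0
    for feat in planted_all:
        planted_genes[feat] = gene_names[cursor : cursor + spec.genes_per_feature]
        cursor += spec.genes_per_feature
    pos_rows = feature_table[feature_table[label_col] == POSITIVE]
    neg_rows = feature_table[feature_table[label_col] == NEGATIVE]
    n_pos, n_neg = len(pos_rows), len(neg_rows)
    r = spec.r_target
    noise_w = float(np.sqrt(1.0 - r * r))

    def z(profile: pd.Series) -> np.ndarray:
        v = profile.to_numpy(dtype=float)
        s = v.std()
        return (v - v.mean()) / (s if s > 0 else 1.0)

    # planted gene profiles: a feature's own standardized positive-class
    # profile, except for auxiliary twins, whose genes load on the
    # standardized MIXTURE of the twin and its partner profile.  A
    # mixture gene then correlates with both features at
    # r*·sqrt((1+c)/2) >= 0.6 whatever their mutual correlation c, which
    # is what makes the pair functionally similar downstream.
    profiles: dict[str, np.ndarray] = {}
    for feat in planted_all:
        if feat in twins:
            mix = z(pos_rows[feat]) + z(pos_rows[twins[feat]])
            s = mix.std()
            profiles[feat] = (mix - mix.mean()) / (s if s > 0 else 1.0)
        else:
            profiles[feat] = z(pos_rows[feat])
    gene_index = {g: i for i, g in enumerate(gene_names)}
    datasets, labels_list = [], []
    for d in range(spec.n_datasets):
        cols = [f"DS{d}_POS{i:03d}" for i in range(n_pos)] + [
            f"DS{d}_NEG{i:03d}" for i in range(n_neg)
        ]
        labels = pd.Series([POSITIVE] * n_pos + [NEGATIVE] * n_neg, index=cols)
        X = spec.baseline + rng.standard_normal((spec.n_genes, n_pos + n_neg))
        for feat in planted_all:
            zf = profiles[feat]
            gi = [gene_index[g] for g in planted_genes[feat]]
            eps = rng.standard_normal((len(gi), n_pos))
            X[np.ix_(gi, range(n_pos))] = spec.baseline + r * zf[None, :] + noise_w * eps
        datasets.append(pd.DataFrame(X, index=gene_names, columns=cols))
        labels_list.append(labels)
    truth = {
        "planted_differential": list(spec.planted_features),
        "aux_twins": twins,
        "planted_genes": planted_genes,
        "r_target": spec.r_target,
    }
    return datasets, labels_list, truth


@dataclass(frozen=True)
class CatalogSpec:
    """Planted gene-set catalog shape.

    Each planted feature receives ``terms_per_feature`` catalog terms
    drawn from its planted gene list; a feature with an auxiliary twin
    shares its terms with the twin (each shared term mixes genes from
    both lists), which is what makes the twin functionally similar.
    Decoy terms are uniform draws from the universe.
    """

    terms_per_feature: int = 10
    # terms are redundant draws from the 30-gene planted lists; the high
    # per-term coverage keeps a term detectable even when a handful of
    # its genes are lost to chance negative-class hits
    genes_per_term: int = 20
    n_decoy_terms: int = 30
    decoy_size: tuple[int, int] = (10, 30)


def generate_catalog(
    genes: list[str],
    truth: dict,
    spec: CatalogSpec | None = None,
    seed: int = 0,
) -> tuple[GeneSetCollection, dict]:
    """Build a GMT-style catalog with planted and decoy terms.

    Returns the catalog and a truth record mapping each planted feature
    to its planted term names (twins share their partner's terms).
    """
    spec = spec or CatalogSpec()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(2,)))
    planted_genes: dict[str, list[str]] = truth["planted_genes"]
    twins: dict[str, str] = truth.get("aux_twins", {})
    partner_of = {partner: aux for aux, partner in twins.items()}
    terms: dict[str, frozenset[str]] = {}
    planted_terms: dict[str, list[str]] = {f: [] for f in planted_genes}
    for feat in truth["planted_differential"]:
        aux = partner_of.get(feat)
        # shared pair terms are drawn from the twin's mixture-gene list,
        # which is positive-specific for BOTH members of the pair
        pool = planted_genes[aux] if aux else planted_genes[feat]
        if spec.genes_per_term > len(pool):
            raise ValueError(
                f"genes_per_term ({spec.genes_per_term}) exceeds the planted "
                f"list size ({len(pool)}) for {feat!r}"
            )
        for t in range(spec.terms_per_feature):
            members = list(rng.choice(pool, spec.genes_per_term, replace=False))
            name = f"TERM_{feat}_{t}"
            terms[name] = frozenset(members)
            planted_terms[feat].append(name)
            if aux:
                planted_terms[aux].append(name)
    for d in range(spec.n_decoy_terms):
        size = int(rng.integers(spec.decoy_size[0], spec.decoy_size[1] + 1))
        terms[f"DECOY_{d:03d}"] = frozenset(rng.choice(genes, size, replace=False))
    # anchor the universe so it is exactly the gene pool
    leftovers = sorted(set(genes) - set().union(*terms.values()))
    if leftovers:
        terms["BACKGROUND_REST"] = frozenset(leftovers)
    catalog = GeneSetCollection(terms=terms)
    return catalog, {"planted_terms": planted_terms}


def simulate(
    out_dir: Path | str,
    seed: int = 0,
    null: bool = False,
    n_patients_per_class: int = 60,
    phantom_spec: PhantomSpec | None = None,
    expression_spec: ExpressionSpec | None = None,
    catalog_spec: CatalogSpec | None = None,
    extraction_config: ExtractionConfig | None = None,
) -> dict:
    """Write a complete synthetic study to ``out_dir``.

    Produces images/, masks/, manifest.csv, features.csv (per image),
    expr_<d>.tsv and expr_labels_<d>.csv per dataset, catalog.gmt and
    truth.json.  With ``null=True`` the two phantom classes share the
    same smoothing scale (no planted class effect).  Returns the truth
    record.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pspec = phantom_spec or PhantomSpec()
    if null:
        pspec = PhantomSpec(
            image_size=pspec.image_size,
            gamma_shape=pspec.gamma_shape,
            gamma_scale=pspec.gamma_scale,
            smoothing_positive=pspec.smoothing_negative,
            smoothing_negative=pspec.smoothing_negative,
            images_per_patient=pspec.images_per_patient,
            ellipse_radii=pspec.ellipse_radii,
            radii_jitter=pspec.radii_jitter,
        )
    images, manifest = generate_phantoms(n_patients_per_class, pspec, seed, out_dir)
    cfg = extraction_config or ExtractionConfig()
    rows = []
    for img, (_, meta) in zip(images, manifest.iterrows()):
        rows.append(
            {"image_id": meta.image_id, "patient_id": meta.patient_id,
             "label": meta.label, **extract_features(img, cfg)}
        )
    features = pd.DataFrame(rows)
    features.to_csv(out_dir / "features.csv", index=False)
    per_patient = aggregate_patients(features)
    feature_cols = [c for c in per_patient.columns if c not in ("patient_id", "label")]
    normalized = per_patient.copy()
    normalized[feature_cols] = max_normalize(per_patient[feature_cols])
    espec = expression_spec or ExpressionSpec()
    datasets, labels_list, truth = generate_expression(normalized, espec, seed)
    for d, (expr, labels) in enumerate(zip(datasets, labels_list)):
        expr.to_csv(out_dir / f"expr_{d}.tsv", sep="\t")
        labels.rename("label").to_csv(out_dir / f"expr_labels_{d}.csv",
                                      index_label="sample")
    catalog, cat_truth = generate_catalog(
        list(datasets[0].index), truth, catalog_spec, seed
    )
    write_gmt(catalog, out_dir / "catalog.gmt")
    truth = {**truth, **cat_truth, "null": null, "seed": int(seed)}
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth
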