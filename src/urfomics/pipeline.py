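"""End-to-end orchestration of the six analysis stages.

Stage order: extract -> differential -> associate -> enrich -> module ->
classify.  Each stage writes its output into the run directory and the
next stage consumes it, so stages are individually re-runnable from
saved intermediates.  A provenance record (config, seed, output
checksums) is written at the end.

The in-memory entry point is :func:`run_analysis` (DataFrames in,
results out); :func:`run_pipeline` is the file-based wrapper driven by a
validated configuration mapping (YAML or JSON).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .association import AssociationResult, PerturbationConfig, identify_specific_genes
from .classify import LogisticModel, SplitScheme, compare_feature_sets
from .enrichment import GeneSetCollection, enrich_feature, read_gmt
from .images import find_image_mask_pairs, load_roi_image
from .module_mining import UrfModule, build_module, find_auxiliary
from .stats import aggregate_patients, max_normalize, select_differential
from .texture import ExtractionConfig, extract_features

__all__ = ["PipelineConfig", "run_analysis", "run_pipeline", "load_config"]

_SCHEMA: dict[str, set[str]] = {
    "inputs": {"images", "masks", "manifest", "features", "expression",
               "expression_labels", "catalog"},
    "extraction": {"n_bins", "connectivity"},
    "differential": {"p_threshold", "fc_threshold"},
    "association": {"n_perturbations", "min_hits", "r_threshold",
                    "p_threshold", "subsample_size", "pairing"},
    "enrichment": {"p_threshold", "adjust"},
    "module": {"simpson_threshold"},
    "classification": {"train_fraction", "n_repeats", "l2"},
}
_TOP_KEYS = set(_SCHEMA) | {"output_dir", "seed"}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    inputs: dict
    output_dir: str
    seed: int = 0
    extraction: dict = field(default_factory=dict)
    differential: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    module: dict = field(default_factory=dict)
    classification: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for block in ("inputs", "output_dir"):
            if block not in raw:
                raise ValueError(f"missing required config block: {block!r}")
        for block, allowed in _SCHEMA.items():
            sub = raw.get(block, {})
            extra = set(sub) - allowed
            if extra:
                raise ValueError(f"unknown keys in {block!r}: {sorted(extra)}")
        return cls(**{k: raw[k] for k in raw})


def load_config(path: Path | str) -> PipelineConfig:
    """Read a YAML or JSON pipeline configuration file."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    return PipelineConfig.from_mapping(raw)


def _meta_cols(df: pd.DataFrame) -> list[str]:
    return [c for c in ("image_id", "patient_id", "label") if c in df.columns]


def run_analysis(
    features: pd.DataFrame,
    expr_datasets: list[pd.DataFrame],
    expr_labels: list[pd.Series],
    catalog: GeneSetCollection,
    seed: int = 0,
    differential_kw: dict | None = None,
    association_kw: dict | None = None,
    enrichment_kw: dict | None = None,
    simpson_threshold: float = 0.6,
    classification_kw: dict | None = None,
) -> dict:
    """Run differential -> association -> enrichment -> module -> classify
    on an in-memory per-image (or per-patient) feature table.

    Returns a dict with the per-patient normalized table, differential
    results, :class:`AssociationResult`, per-feature function sets,
    enrichment rows, the :class:`UrfModule` and the paired classifier
    comparison.
    """
    differential_kw = differential_kw or {}
    enrichment_kw = enrichment_kw or {}
    classification_kw = dict(classification_kw or {})
    # per-patient table on the max-normalized scale
    per_patient = (
        aggregate_patients(features) if "image_id" in features.columns else features
    )
    feature_cols = [c for c in per_patient.columns if c not in _meta_cols(per_patient)]
    normalized = per_patient.copy()
    normalized[feature_cols] = max_normalize(per_patient[feature_cols])
    diff_results = select_differential(normalized, **differential_kw)
    differential = [r.feature for r in diff_results if r.selected]
    if not differential:
        raise RuntimeError("stage 'differential': no feature passed selection")
    # expression matrices on the same normalized scale (per gene row)
    norm_expr = [max_normalize(d.T).T for d in expr_datasets]
    assoc_cfg = PerturbationConfig(seed=seed, **(association_kw or {}))
    assoc = identify_specific_genes(normalized, norm_expr, expr_labels, assoc_cfg)
    # function sets for every feature with a nonempty specific gene set
    function_sets: dict[str, set[str]] = {}
    p_sums: dict[str, float] = {}
    enrich_rows = []
    for feat, genes in assoc.positive_specific.items():
        if not genes:
            function_sets[feat] = set()
            continue
        results = enrich_feature(genes, catalog, feature=feat, **enrichment_kw)
        enrich_rows.extend(results)
        function_sets[feat] = {r.term for r in results if r.enriched}
        p_sums[feat] = float(sum(r.p_value for r in results if r.enriched))
    diff_sets = {f: function_sets.get(f, set()) for f in differential}
    aux = find_auxiliary(
        {f: s for f, s in diff_sets.items() if s},
        function_sets,
        threshold=simpson_threshold,
        partner_scores=p_sums,
    )
    module = build_module(differential, aux)
    # classifier comparison: differential set vs full module, same splits
    l2 = classification_kw.pop("l2", 1.0)
    scheme = SplitScheme(seed=seed, **classification_kw)
    y = (normalized["label"] == "positive").to_numpy(int)
    X_diff = normalized[differential].to_numpy(float)
    X_module = normalized[list(module.features)].to_numpy(float)
    comparison = compare_feature_sets(
        X_diff, X_module, y, model_factory=lambda: LogisticModel(l2=l2), scheme=scheme
    )
    return {
        "per_patient": normalized,
        "differential_results": diff_results,
        "differential": differential,
        "association": assoc,
        "function_sets": function_sets,
        "enrichment": enrich_rows,
        "module": module,
        "comparison": comparison,
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def extract_feature_table(
    image_dir: Path | str,
    mask_dir: Path | str,
    manifest: pd.DataFrame | None = None,
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Extract the 86 features for every image/mask pair in a directory."""
    pairs = find_image_mask_pairs(image_dir, mask_dir)
    meta = {}
    if manifest is not None:
        meta = manifest.set_index("image_id").to_dict("index")
    rows = []
    for img_path, mask_path in pairs:
        image_id = img_path.stem
        info = meta.get(image_id, {})
        roi = load_roi_image(img_path, mask_path, image_id=image_id,
                             patient_id=str(info.get("patient_id", image_id)))
        row = {"image_id": image_id, "patient_id": roi.patient_id}
        if "label" in info:
            row["label"] = info["label"]
        row.update(extract_features(roi, config))
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages from files per the config; write stage outputs
    and a provenance record into the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = config.inputs
    stage = "extract"
    try:
        if inputs.get("features"):
            features = pd.read_csv(inputs["features"])
        else:
            manifest = pd.read_csv(inputs["manifest"]) if inputs.get("manifest") else None
            ext = ExtractionConfig(**config.extraction)
            features = extract_feature_table(
                inputs["images"], inputs["masks"], manifest, ext
            )
        features.to_csv(out / "features.csv", index=False)
        stage = "load-expression"
        expr_paths = inputs["expression"]
        label_paths = inputs["expression_labels"]
        if isinstance(expr_paths, str):
            expr_paths, label_paths = [expr_paths], [label_paths]
        expr = [pd.read_csv(p, sep="\t", index_col=0) for p in expr_paths]
        labels = [
            pd.read_csv(p, index_col=0)["label"] for p in label_paths
        ]
        catalog = read_gmt(inputs["catalog"])
        stage = "analysis"
        res = run_analysis(
            features,
            expr,
            labels,
            catalog,
            seed=int(config.seed),
            differential_kw=config.differential,
            association_kw=config.association,
            enrichment_kw=config.enrichment,
            simpson_threshold=float(config.module.get("simpson_threshold", 0.6)),
            classification_kw=config.classification,
        )
        stage = "write-outputs"
        pd.DataFrame(
            [dataclasses.asdict(r) for r in res["differential_results"]]
        ).to_csv(out / "diff.csv", index=False)
        assoc: AssociationResult = res["association"]
        assoc_json = {
            feat: {
                "positive_specific": sorted(genes),
                "hit_counts": {
                    g: int(assoc.hit_counts_positive.loc[feat, g]) for g in sorted(genes)
                },
                "mean_r": {
                    g: float(assoc.mean_r_positive.loc[feat, g]) for g in sorted(genes)
                },
            }
            for feat, genes in assoc.positive_specific.items()
        }
        (out / "assoc.json").write_text(json.dumps(assoc_json, indent=1))
        pd.DataFrame([dataclasses.asdict(r) for r in res["enrichment"]]).to_csv(
            out / "enrich.csv", index=False
        )
        module: UrfModule = res["module"]
        (out / "module.json").write_text(json.dumps({
            "differential": list(module.differential_features),
            "auxiliary": list(module.auxiliary_features),
            "edges": [list(e) for e in module.edges],
        }, indent=2))
        pd.DataFrame(module.edges, columns=["source", "target", "sim"]).to_csv(
            out / "module_edges.csv", index=False
        )
        comp = res["comparison"]
        (out / "eval.json").write_text(json.dumps({
            "mean_auc_differential": comp["mean_auc_differential"],
            "mean_auc_module": comp["mean_auc_module"],
            "mean_delta_auc": comp["mean_delta_auc"],
            "auc_differential": list(map(float, comp["auc_differential"])),
            "auc_module": list(map(float, comp["auc_module"])),
        }, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    provenance = {
        "seed": int(config.seed),
        "config": dataclasses.asdict(config),
        "checksums": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*"))
            if p.is_file() and p.name != "provenance.json"
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    res["provenance"] = provenance
    return res
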