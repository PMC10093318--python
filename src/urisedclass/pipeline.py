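"""End-to-end pipeline orchestration and run configuration.

Stage order: load (or synthesize) images -> extract the texture and dense
feature blocks -> mRMR-select ``k`` features from each -> fuse -> evaluate
each configured classifier -> write the metrics report.  Every stage's
seed derives deterministically from the global seed, every intermediate is
persisted as CSV/JSON next to a config sidecar, and a manifest records
shapes, seeds and content hashes, so identical configs reproduce identical
reports byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import ClassifierSpec, EvalScheme, fuse, subselect, train_eval
from .containers import FeatureMatrix
from .dataset import ImageRecord, load_image_folder
from .deepfeat import FeatureExtractorSpec, extract_deep_features
from .lbp import LBPConfig, lbp_feature_vector
from .metrics import render_report
from .mrmr import mrmr_select
from .synthgen import SyntheticDatasetSpec, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "extract_lbp_features",
           "extract_and_fuse"]

logger = logging.getLogger(__name__)


def _derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def extract_lbp_features(records: list[ImageRecord],
                         config: LBPConfig = LBPConfig()) -> FeatureMatrix:
    """Texture feature block for a list of records (rows keep input order)."""
    values = np.stack([lbp_feature_vector(r.image, config) for r in records])
    return FeatureMatrix(
        values=values,
        sample_ids=[r.sample_id for r in records],
        labels=[r.label for r in records],
        feature_names=[f"lbp:f{i:04d}" for i in range(values.shape[1])],
    )


def extract_and_fuse(records: list[ImageRecord], k: int = 500, seed: int = 0,
                     lbp_config: LBPConfig = LBPConfig(),
                     criterion: str = "MID", bins: int = 10) -> FeatureMatrix:
    """Convenience: both blocks -> mRMR(k) each -> fused matrix."""
    lbp_fm = extract_lbp_features(records, lbp_config)
    deep_fm = extract_deep_features(
        records, FeatureExtractorSpec(seed=_derive_seed(seed, "deep")))
    sel_lbp = mrmr_select(lbp_fm, k=min(k, lbp_fm.n_features),
                          criterion=criterion, bins=bins)
    sel_deep = mrmr_select(deep_fm, k=min(k, deep_fm.n_features),
                           criterion=criterion, bins=bins)
    return fuse(subselect(lbp_fm, sel_lbp), subselect(deep_fm, sel_deep))


@dataclass
class PipelineConfig:
    """Serializable description of a full pipeline run."""

    dataset_dir: str | None = None
    synthetic: SyntheticDatasetSpec | None = None
    synthetic_scale: float = 1.0
    lbp: LBPConfig = field(default_factory=LBPConfig)
    deep: FeatureExtractorSpec = field(default_factory=FeatureExtractorSpec)
    k_per_block: int = 500
    criterion: str = "MID"
    bins: int = 10
    nested: bool = False
    classifiers: tuple[str, ...] = (
        "fine_tree", "linear_discriminant", "gaussian_naive_bayes",
        "svm", "knn", "ensemble_bagged_trees",
    )
    scheme: EvalScheme = field(default_factory=EvalScheme)
    output_dir: str = "pipeline_out"
    seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(_to_jsonable(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        return _config_from_dict(raw)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _config_from_dict(raw: dict) -> PipelineConfig:
    from .synthgen import ClassSpec

    synth = raw.get("synthetic")
    if synth is not None:
        synth = SyntheticDatasetSpec(
            class_specs=[ClassSpec(**c) for c in synth["class_specs"]],
            image_size=tuple(synth["image_size"]),
            seed=synth["seed"],
        )
    return PipelineConfig(
        dataset_dir=raw.get("dataset_dir"),
        synthetic=synth,
        synthetic_scale=raw.get("synthetic_scale", 1.0),
        lbp=LBPConfig(**raw["lbp"]),
        deep=FeatureExtractorSpec(
            **{**raw["deep"], "input_size": tuple(raw["deep"]["input_size"])}),
        k_per_block=raw["k_per_block"],
        criterion=raw["criterion"],
        bins=raw["bins"],
        nested=raw.get("nested", False),
        classifiers=tuple(raw["classifiers"]),
        scheme=EvalScheme(**raw["scheme"]),
        output_dir=raw["output_dir"],
        seed=raw["seed"],
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns paths of the report files."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    manifest: dict = {"seed": config.seed, "stages": {}}

    # --- load ---------------------------------------------------------
    if config.dataset_dir is not None:
        records = load_image_folder(config.dataset_dir)
    elif config.synthetic is not None:
        spec = config.synthetic
        if config.synthetic_scale != 1.0:
            spec = spec.scaled(config.synthetic_scale)
        records = generate_dataset(spec)
    else:
        raise ValueError("config needs dataset_dir or a synthetic spec")
    logger.info("stage load: %d records, %d classes",
                len(records), len({r.label for r in records}))
    manifest["stages"]["load"] = {"n_records": len(records)}

    # --- extract ------------------------------------------------------
    lbp_fm = extract_lbp_features(records, config.lbp)
    deep_spec = dataclasses.replace(
        config.deep, seed=_derive_seed(config.seed, "deep"))
    deep_fm = extract_deep_features(records, deep_spec)
    lbp_fm.to_csv(out / "features_lbp.csv")
    deep_fm.to_csv(out / "features_deep.csv")
    logger.info("stage extract: lbp %s, deep %s",
                lbp_fm.values.shape, deep_fm.values.shape)
    manifest["stages"]["extract"] = {
        "lbp_shape": list(lbp_fm.values.shape),
        "deep_shape": list(deep_fm.values.shape),
    }

    # --- select + fuse ------------------------------------------------
    if config.k_per_block > min(lbp_fm.n_features, deep_fm.n_features):
        raise ValueError(
            f"k_per_block={config.k_per_block} exceeds a block's feature count "
            f"({lbp_fm.n_features} lbp, {deep_fm.n_features} deep)"
        )
    sel_lbp = mrmr_select(lbp_fm, config.k_per_block, config.criterion, config.bins)
    sel_deep = mrmr_select(deep_fm, config.k_per_block, config.criterion, config.bins)
    (out / "selected_lbp.json").write_text(json.dumps(sel_lbp.to_dict(), indent=1))
    (out / "selected_deep.json").write_text(json.dumps(sel_deep.to_dict(), indent=1))
    fused = fuse(subselect(lbp_fm, sel_lbp), subselect(deep_fm, sel_deep))
    fused.to_csv(out / "features_fused.csv")
    logger.info("stage select+fuse: %s -> %s x %d fused",
                lbp_fm.values.shape, fused.n_samples, fused.n_features)
    manifest["stages"]["fuse"] = {"fused_shape": list(fused.values.shape)}

    # --- classify -----------------------------------------------------
    results = {}
    scheme = dataclasses.replace(
        config.scheme, seed=_derive_seed(config.seed, "eval"))
    for kind in config.classifiers:
        spec = ClassifierSpec(kind=kind, seed=_derive_seed(config.seed, kind))
        if config.nested:
            # leakage-free variant: mRMR re-run inside each training fold
            from .classify import train_eval_nested
            pooled, per_fold = train_eval_nested(
                [lbp_fm, deep_fm], config.k_per_block, spec, scheme,
                config.criterion, config.bins)
        else:
            pooled, per_fold = train_eval(fused, spec, scheme)
        results[kind] = pooled
        (out / f"result_{kind}.json").write_text(json.dumps({
            "classifier": kind,
            "spec": spec.resolved(),
            "scheme": _to_jsonable(scheme),
            "pooled": pooled.to_dict(),
            "folds": [cm.to_dict() for cm in per_fold],
        }, indent=1))
    logger.info("stage classify: %d classifiers evaluated", len(results))

    # --- report -------------------------------------------------------
    paths = render_report(results, out)
    manifest["hashes"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.suffix in (".csv", ".json", ".txt") and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    paths["manifest"] = out / "manifest.json"
    return paths
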