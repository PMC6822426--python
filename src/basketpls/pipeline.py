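"""End-to-end pipeline: curate -> split -> fit -> signature -> compare -> perturb.

Driven by a flat config (YAML/JSON on disk or a plain dict). Every stage
logs its input/output shapes and contributes to a run manifest written
alongside the artifacts, so a run is reproducible from the manifest
alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import curation
from .benchmark import loocv_compare, run_baselines
from .datatypes import FeatureMatrix, ResponseVector
from .opls import compute_vip, fit_opls, predict
from .perturbation import build_receptor_model, simulate_inhibition
from .signature import select_signature

log = logging.getLogger(__name__)

SUBSET_SELECTORS = ("all", "total_only", "phospho_only", "receptor_only")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Flat configuration; defaults follow the study's stated settings."""

    matrix_path: str = ""
    response_path: str = ""
    sample_meta_path: str | None = None
    annotation_path: str | None = None
    detection_threshold: float = 0.25
    resistance_threshold: float = 0.2
    folds: int = 7
    delta_q2: float = 0.05
    max_orthogonal: int = 5
    test_n: int = 6
    seed: int = 0
    feature_subset: str | list[str] = "all"
    compare_models: list[str] = field(default_factory=list)
    loocv: bool = False
    perturb_targets: list[str] = field(default_factory=list)
    perturb_samples: list[str] = field(default_factory=list)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        if not 0 < self.detection_threshold <= 1:
            raise PipelineError("config", "detection_threshold must be in (0, 1]")
        if not 0 < self.resistance_threshold < 1:
            raise PipelineError("config", "resistance_threshold must be in (0, 1)")
        if isinstance(self.feature_subset, str) and \
                self.feature_subset not in SUBSET_SELECTORS:
            raise PipelineError(
                "config",
                f"feature_subset must be one of {SUBSET_SELECTORS} or an id list",
            )
        for p, name in ((self.matrix_path, "matrix_path"),
                        (self.response_path, "response_path")):
            if not p or not Path(p).exists():
                raise PipelineError("config", f"{name} not found: {p!r}")


def _apply_subset(x: FeatureMatrix, selector) -> FeatureMatrix:
    if isinstance(selector, (list, tuple)):
        return x.subset_features(list(selector))
    if selector == "all":
        return x
    meta = x.feature_meta
    if selector == "total_only":
        keep = meta.index[meta["kind"] == "total"]
    elif selector == "phospho_only":
        keep = meta.index[meta["kind"] == "phospho"]
    elif selector == "receptor_only":
        keep = meta.index[meta["is_receptor"]]
    else:
        raise PipelineError("curate", f"unknown feature subset {selector!r}")
    if keep.empty:
        raise PipelineError("curate", f"subset {selector!r} matches no feature")
    return x.subset_features(keep.tolist())


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the configured stages, writing artifacts into ``out_dir``.

    Returns the run directory. On a stage failure, artifacts produced so
    far are kept next to a ``FAILED`` marker naming the stage.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": [],
    }
    stage = "curate"
    try:
        x = curation.read_feature_matrix(
            config.matrix_path,
            annotation_path=config.annotation_path,
            sample_meta_path=config.sample_meta_path,
        )
        y = curation.read_response(config.response_path)
        x, y = curation.intersect_datasets(x, y)
        x = curation.filter_by_detection(x, config.detection_threshold)
        x = _apply_subset(x, config.feature_subset)
        x = curation.impute_missing(x)
        scaled, params = curation.autoscale(x)
        manifest["stages"].append(
            {"stage": stage, "n_samples": scaled.shape[0],
             "n_features": scaled.shape[1]}
        )
        log.info("curate: %d samples x %d features", *scaled.shape)

        stage = "split"
        split = curation.stratified_split(
            scaled, y, test_n=config.test_n, seed=config.seed,
            resistance_threshold=config.resistance_threshold,
        )
        (out / "split.json").write_text(json.dumps(
            {"train": split.train_ids, "test": split.test_ids}, indent=1))
        manifest["stages"].append(
            {"stage": stage, "n_train": len(split.train_ids),
             "n_test": len(split.test_ids)}
        )

        stage = "fit"
        x_tr = scaled.subset_samples(split.train_ids)
        y_tr = y.subset(split.train_ids)
        x_te = scaled.subset_samples(split.test_ids)
        y_te = y.subset(split.test_ids)
        # refit scaling on the training rows only so the test set stays unseen
        x_tr_raw = x.subset_samples(split.train_ids)
        scaled_tr, params_tr = curation.autoscale(x_tr_raw)
        model = fit_opls(
            scaled_tr, y_tr, max_orthogonal=config.max_orthogonal,
            folds=config.folds, delta_q2=config.delta_q2, seed=config.seed,
            scaling=params_tr,
        )
        model.to_json(out / "model.json")
        test_pred = predict(model, x.subset_samples(split.test_ids))
        test_pred.rename("predicted").to_frame().assign(
            observed=y_te.auc).to_csv(out / "test_predictions.tsv", sep="\t")
        manifest["stages"].append(
            {"stage": stage, "R2Y": model.stats["R2Y"], "Q2Y": model.stats["Q2Y"],
             "n_orthogonal": model.n_orthogonal}
        )

        stage = "vip"
        vip = compute_vip(model)
        vip.to_csv(out / "vip.tsv", sep="\t")
        sig = select_signature(vip)
        sig.to_csv(out / "signature.tsv", sep="\t")
        manifest["stages"].append(
            {"stage": stage, "n_vip_gt1": int((vip["VIP"] > 1).sum())}
        )

        if config.compare_models:
            stage = "compare"
            opls_kwargs = {"folds": config.folds, "delta_q2": config.delta_q2,
                           "max_orthogonal": config.max_orthogonal,
                           "seed": config.seed}
            # all baselines see the training-fold scaling, like the O-PLS fit
            x_te_scaled = FeatureMatrix(
                params_tr.transform(x.subset_samples(split.test_ids).values),
                x.feature_meta.copy(), x_te.sample_meta.copy(),
            )
            report = run_baselines(
                (scaled_tr, y_tr), (x_te_scaled, y_te), config.compare_models,
                seed=config.seed, opls_kwargs=opls_kwargs,
            )
            if config.loocv:
                report_loo = loocv_compare(
                    scaled, y, config.compare_models, reference="opls",
                    seed=config.seed, opls_kwargs=opls_kwargs,
                )
                (out / "loocv_report.json").write_text(
                    json.dumps(report_loo.to_json_dict(), indent=1))
                report_loo.to_frame().to_csv(out / "loocv_report.tsv", sep="\t",
                                             index=False)
            report.to_frame().to_csv(out / "comparison.tsv", sep="\t", index=False)
            (out / "comparison.json").write_text(
                json.dumps(report.to_json_dict(), indent=1))
            manifest["stages"].append(
                {"stage": stage,
                 "rmse": {m: rec["rmse"] for m, rec in report.models.items()}}
            )

        if config.perturb_targets:
            stage = "perturb"
            rec_model, rec_x = build_receptor_model(
                x, y, folds=config.folds, delta_q2=config.delta_q2,
                seed=config.seed,
            )
            samples = config.perturb_samples or y.sample_ids
            result = simulate_inhibition(
                rec_model, rec_x, samples, config.perturb_targets,
                training_x=rec_x,
            )
            result.table.to_csv(out / "perturbation.tsv", sep="\t")
            manifest["stages"].append(
                {"stage": stage, "n_targets": len(config.perturb_targets),
                 "n_samples": len(samples)}
            )
    except Exception as exc:
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
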