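"""In-silico receptor inhibition on a fitted O-PLS model.

The receptor-only model regresses drug sensitivity on the receptor
expression/phosphorylation subset of the matrix, trained on all samples.
Inhibition of a receptor is simulated by clamping its features to the
minimum value observed across the training matrix (the lowest abundance
any profiled line showed), re-applying the model, and reporting the
predicted change in sensitivity AUC per target sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .datatypes import FeatureMatrix, ResponseVector
from .opls import ModelError, OplsModel, fit_opls, predict
from .curation import autoscale, impute_missing

log = logging.getLogger(__name__)


def build_receptor_model(
    x: FeatureMatrix,
    y: ResponseVector,
    folds: int = 7,
    delta_q2: float = 0.05,
    seed: int = 0,
) -> tuple[OplsModel, FeatureMatrix]:
    """Fit an O-PLS model on the receptor-flagged feature subset only.

    All samples are used for training (no held-out set). Returns the
    model together with the raw-scale receptor matrix it was trained on,
    which supplies the clamp minima for :func:`simulate_inhibition`.
    """
    receptor_ids = x.feature_meta.index[x.feature_meta["is_receptor"]].tolist()
    if not receptor_ids:
        raise ModelError("no receptor-flagged features in the matrix")
    log.info("receptor-only model over %d features", len(receptor_ids))
    sub = x.subset_features(receptor_ids)
    if sub.values.isna().any().any():
        sub = impute_missing(sub)
    scaled, params = autoscale(sub)
    model = fit_opls(scaled, y, folds=folds, delta_q2=delta_q2, seed=seed,
                     scaling=params)
    return model, sub.subset_features(model.feature_ids)


@dataclass
class PerturbationResult:
    """Baseline vs clamped predictions for each target sample."""

    table: pd.DataFrame  # index sample_id; baseline, perturbed, delta
    target_features: list[str]
    clamp_values: pd.Series = field(default_factory=pd.Series)


def simulate_inhibition(
    model: OplsModel,
    x: FeatureMatrix,
    target_samples: list[str],
    target_features: list[str],
    training_x: FeatureMatrix | None = None,
) -> PerturbationResult:
    """Clamp target features to their training minima and re-predict.

    ``training_x`` supplies the raw-scale matrix the clamp minima are
    taken from; it defaults to ``x`` restricted to the model's training
    samples. Only the requested features change — correlated features are
    deliberately left untouched so the perturbation is exactly the one
    asked for.
    """
    unknown_s = [s for s in target_samples if s not in x.values.index]
    unknown_f = [f for f in target_features if f not in model.feature_ids]
    if unknown_s or unknown_f:
        raise ModelError(
            f"unknown sample ids {unknown_s} / feature ids {unknown_f}"
        )
    if not target_features:
        log.warning("empty target feature list: perturbation is the identity")

    if training_x is None:
        train_ids = [s for s in model.sample_ids if s in x.values.index]
        training_x = x.subset_samples(train_ids) if train_ids else x
    minima = training_x.values[list(target_features)].min(axis=0) if target_features \
        else pd.Series(dtype=float)

    base = x.subset_samples(target_samples)
    baseline = predict(model, base)
    clamped_vals = base.values.copy()
    for f in target_features:
        clamped_vals[f] = minima[f]
    clamped = FeatureMatrix(clamped_vals, base.feature_meta.copy(),
                            base.sample_meta.copy())
    perturbed = predict(model, clamped)

    table = pd.DataFrame(
        {
            "baseline": baseline,
            "perturbed": perturbed,
            "delta": perturbed - baseline,
        }
    )
    table.index.name = "sample_id"
    return PerturbationResult(
        table=table, target_features=list(target_features), clamp_values=minima
    )
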