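"""Benchmarking O-PLS against standard regression baselines.

The comparison protocols mirror the study design: a stratified
train/test split scored by test RMSE, and per-sample leave-one-out
errors compared model-vs-reference with an exact two-sided binomial sign
test. Baselines are LASSO with internal 5-fold CV, random forest
(100 trees, predictions averaged over 5 seeds), and support-vector
regression with linear and quadratic-polynomial kernels; all consume the
same autoscaled matrix as O-PLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LassoCV
from sklearn.svm import SVR

from .datatypes import FeatureMatrix, ResponseVector
from .opls import fit_opls, predict

KNOWN_MODELS = ("opls", "lasso_cv", "random_forest", "svr_linear", "svr_quadratic")

RF_SEEDS = (0, 1, 2, 3, 4)
RF_TREES = 100
SVR_C = 1.0
SVR_EPS = 0.1
LASSO_CV_FOLDS = 5


class BenchmarkError(ValueError):
    pass


def rmse(predicted, observed) -> float:
    """Root mean squared prediction error."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise BenchmarkError("predicted and observed must be equal-length vectors")
    if predicted.size == 0:
        raise BenchmarkError("empty vectors")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def exact_binomial_test(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value.

    Sums the probabilities of all outcomes whose likelihood under
    Binomial(n, p0) does not exceed that of the observed count (the
    standard minlike two-sided rule).
    """
    if not (0 <= k <= n) or n < 1:
        raise BenchmarkError(f"invalid counts k={k}, n={n}")
    if not 0 < p0 < 1:
        raise BenchmarkError("p0 must be in (0, 1)")
    pmf = binom.pmf(np.arange(n + 1), n, p0)
    return float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-12)].sum()))


def _fit_predict(name: str, Xtr, ytr, Xte, seed: int = 0,
                 opls_kwargs: dict | None = None,
                 feature_ids=None, train_ids=None, test_ids=None):
    """Fit one named model on arrays and predict the test rows."""
    if name == "opls":
        fm = FeatureMatrix(pd.DataFrame(Xtr, index=train_ids, columns=feature_ids))
        rv = ResponseVector(pd.Series(ytr, index=train_ids))
        model = fit_opls(fm, rv, **(opls_kwargs or {}))
        te = FeatureMatrix(pd.DataFrame(Xte, index=test_ids, columns=feature_ids))
        return predict(model, te).to_numpy(), {"n_orthogonal": model.n_orthogonal}
    if name == "lasso_cv":
        est = LassoCV(cv=LASSO_CV_FOLDS, random_state=seed, max_iter=50000)
        est.fit(Xtr, ytr)
        return est.predict(Xte), {"alpha": float(est.alpha_)}
    if name == "random_forest":
        preds = np.zeros(Xte.shape[0])
        for s in RF_SEEDS:
            est = RandomForestRegressor(n_estimators=RF_TREES, random_state=s)
            est.fit(Xtr, ytr)
            preds += est.predict(Xte)
        return preds / len(RF_SEEDS), {"seeds": list(RF_SEEDS), "trees": RF_TREES}
    if name == "svr_linear":
        est = SVR(kernel="linear", C=SVR_C, epsilon=SVR_EPS)
        est.fit(Xtr, ytr)
        return est.predict(Xte), {"C": SVR_C, "epsilon": SVR_EPS}
    if name == "svr_quadratic":
        est = SVR(kernel="poly", degree=2, C=SVR_C, epsilon=SVR_EPS)
        est.fit(Xtr, ytr)
        return est.predict(Xte), {"C": SVR_C, "epsilon": SVR_EPS, "degree": 2}
    raise BenchmarkError(f"unknown model {name!r}; choose from {KNOWN_MODELS}")


@dataclass
class ComparisonReport:
    """Per-model predictions, errors and reference comparisons."""

    models: dict = field(default_factory=dict)  # name -> record
    reference: str | None = None
    protocol: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, rec in self.models.items():
            row = {"model": name, "rmse": rec["rmse"]}
            if "wins_vs_reference" in rec:
                row.update(
                    wins_vs_reference=rec["wins_vs_reference"],
                    n=rec["n"],
                    binomial_p=rec["binomial_p"],
                    ties=rec.get("ties", 0),
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        out = {"reference": self.reference, "protocol": self.protocol, "models": {}}
        for name, rec in self.models.items():
            out["models"][name] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in rec.items()
                if k != "predictions_series"
            }
        return out


def run_baselines(
    train: tuple[FeatureMatrix, ResponseVector],
    test: tuple[FeatureMatrix, ResponseVector],
    model_specs=("opls", "lasso_cv", "random_forest", "svr_linear", "svr_quadratic"),
    seed: int = 0,
    opls_kwargs: dict | None = None,
) -> ComparisonReport:
    """Fit every named model on the training set and score test RMSE."""
    model_specs = list(model_specs)
    if not model_specs:
        raise BenchmarkError("empty model list")
    x_tr, y_tr = train
    x_te, y_te = test
    feats = x_tr.feature_ids
    Xtr = x_tr.values.loc[y_tr.sample_ids, feats].to_numpy(dtype=float)
    Xte = x_te.values.loc[y_te.sample_ids, feats].to_numpy(dtype=float)
    ytr = y_tr.auc.to_numpy(dtype=float)
    yte = y_te.auc.to_numpy(dtype=float)

    report = ComparisonReport(protocol="train_test")
    for name in model_specs:
        preds, meta = _fit_predict(
            name, Xtr, ytr, Xte, seed=seed, opls_kwargs=opls_kwargs,
            feature_ids=feats, train_ids=y_tr.sample_ids, test_ids=y_te.sample_ids,
        )
        report.models[name] = {
            "rmse": rmse(preds, yte),
            "predictions": preds,
            "abs_errors": np.abs(preds - yte),
            "sample_ids": y_te.sample_ids,
            "hyperparams": meta,
        }
    return report


def loocv_compare(
    x: FeatureMatrix,
    y: ResponseVector,
    model_specs=("opls", "svr_linear"),
    reference: str = "opls",
    seed: int = 0,
    opls_kwargs: dict | None = None,
) -> ComparisonReport:
    """Leave-one-out comparison of per-sample errors against a reference.

    Every model is refitted on the n-1 remaining samples for each held-out
    sample (hyperparameters re-tuned per fold). For each competitor the
    number of samples where the reference's absolute error is strictly
    smaller is counted; exact ties contribute half a win each and the
    binomial count is rounded to the nearest integer. A two-sided exact
    binomial test against p0 = 0.5 is attached.
    """
    model_specs = list(model_specs)
    if not model_specs:
        raise BenchmarkError("empty model list")
    if reference not in model_specs:
        raise BenchmarkError(f"reference {reference!r} not among models")
    n = len(y.sample_ids)
    if n < 3:
        raise BenchmarkError("need at least 3 samples for LOOCV")
    feats = x.feature_ids
    X = x.values.loc[y.sample_ids, feats].to_numpy(dtype=float)
    yv = y.auc.to_numpy(dtype=float)

    errors = {name: np.zeros(n) for name in model_specs}
    preds = {name: np.zeros(n) for name in model_specs}
    for i in range(n):
        tr = np.setdiff1d(np.arange(n), [i])
        ids_tr = [y.sample_ids[j] for j in tr]
        for name in model_specs:
            ph, _ = _fit_predict(
                name, X[tr], yv[tr], X[[i]], seed=seed, opls_kwargs=opls_kwargs,
                feature_ids=feats, train_ids=ids_tr, test_ids=[y.sample_ids[i]],
            )
            preds[name][i] = ph[0]
            errors[name][i] = abs(ph[0] - yv[i])

    report = ComparisonReport(reference=reference, protocol="loocv")
    ref_err = errors[reference]
    for name in model_specs:
        rec = {
            "rmse": rmse(preds[name], yv),
            "predictions": preds[name],
            "abs_errors": errors[name],
            "sample_ids": y.sample_ids,
        }
        if name != reference:
            wins, ties = count_reference_wins(ref_err, errors[name])
            k = int(round(wins))
            rec.update(
                wins_vs_reference=k,
                ties=ties,
                n=n,
                binomial_p=exact_binomial_test(k, n),
            )
        report.models[name] = rec
    return report


def count_reference_wins(ref_errors, other_errors, tie_tol: float = 1e-12):
    """Count samples where the reference error is strictly smaller.

    Ties (within ``tie_tol``) are split as half-wins; the tie count is
    returned alongside.
    """
    ref_errors = np.asarray(ref_errors, dtype=float)
    other_errors = np.asarray(other_errors, dtype=float)
    ties = int(np.sum(np.abs(ref_errors - other_errors) <= tie_tol))
    strict = int(np.sum(ref_errors < other_errors - tie_tol))
    return strict + 0.5 * ties, ties
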