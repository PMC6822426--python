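"""Orthogonal projections to latent structures (O-PLS) for a scalar response.

O-PLS splits the systematic variation of an autoscaled feature matrix X
into a part correlated with the response y (one predictive component,
since y is scalar) and parts orthogonal to it. Orthogonal components are
extracted NIPALS-style: the candidate loading of the current predictive
component is stripped of its projection onto the y-covariance weight
vector, giving a weight vector w_o with X w_o uncorrelated with y; the
corresponding variation t_o p_o' is removed from X before the predictive
component is finally computed. Each orthogonal component is retained only
if it raises the 7-fold cross-validated Q2Y by more than ``delta_q2``
(0.05 by default).

Variable importance in projection (VIP) summarises each feature's
contribution over the M retained components:

    VIP_j = sqrt( p * sum_m w_mj^2 SS_m / sum_m SS_m )

with SS_m the fraction of y-variance explained by component m and the
per-component weight vectors unit-norm, which forces mean(VIP^2) = 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix, ResponseVector, ScalingParams


class ModelError(ValueError):
    """Raised for ill-posed fits or mismatched model/data inputs."""


# ---------------------------------------------------------------------------
# plain-array NIPALS routines (internal work-horses)
# ---------------------------------------------------------------------------

def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """One-block NIPALS PLS1 on centered arrays.

    Returns dict of stacked weights W (components x p), loadings P, inner
    coefficients b (per component) and scores T (n x components). For a
    scalar response the per-component weight has a closed form
    w = X'y / ||X'y||, so no inner iteration is needed.
    """
    if np.allclose(y, y[0]):
        raise ModelError("zero-variance response")
    Xd = X.copy()
    yd = y.astype(float).copy()
    n, p = X.shape
    W, P, T, b = [], [], [], []
    for _ in range(n_components):
        w = Xd.T @ yd
        nrm = np.linalg.norm(w)
        if nrm < 1e-12:
            break
        w = w / nrm
        t = Xd @ w
        tt = t @ t
        if tt < 1e-12:
            break
        pvec = Xd.T @ t / tt
        bm = (t @ yd) / tt
        Xd = Xd - np.outer(t, pvec)
        yd = yd - bm * t
        W.append(w)
        P.append(pvec)
        T.append(t)
        b.append(bm)
    return {
        "W": np.array(W),
        "P": np.array(P),
        "T": np.array(T).T if T else np.empty((n, 0)),
        "b": np.array(b),
    }


def _pls1_predict(fit: dict, Xnew: np.ndarray) -> np.ndarray:
    """Predict (centered scale) from a ``_nipals_pls1`` fit."""
    Xd = Xnew.copy()
    yhat = np.zeros(Xnew.shape[0])
    for w, pvec, bm in zip(fit["W"], fit["P"], fit["b"]):
        t = Xd @ w
        yhat += bm * t
        Xd = Xd - np.outer(t, pvec)
    return yhat


def _fit_opls_arrays(X: np.ndarray, y: np.ndarray, n_orthogonal: int):
    """Core O-PLS fit on centered arrays with a fixed orthogonal count.

    The y-covariance weight w is computed once from the starting matrix;
    every orthogonal weight is orthogonal to it by construction, so the
    orthogonal scores are exactly uncorrelated with y.
    """
    if np.allclose(y, y[0]):
        raise ModelError("zero-variance response")
    w = X.T @ y
    nrm = np.linalg.norm(w)
    if nrm < 1e-12:
        raise ModelError("response has no covariance with any feature")
    w = w / nrm

    Xd = X.copy()
    W_o, P_o, T_o = [], [], []
    for _ in range(n_orthogonal):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        nrm_o = np.linalg.norm(w_o)
        if nrm_o < 1e-10:  # no orthogonal variation left
            break
        w_o = w_o / nrm_o
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)

    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    b = (t @ y) / (t @ t)
    return {
        "w": w, "p": p, "t": t, "b": b,
        "W_o": np.array(W_o).reshape(len(W_o), -1) if W_o else np.empty((0, X.shape[1])),
        "P_o": np.array(P_o).reshape(len(P_o), -1) if P_o else np.empty((0, X.shape[1])),
        "T_o": np.array(T_o).T if T_o else np.empty((X.shape[0], 0)),
    }


def _opls_filter(fit: dict, Xnew: np.ndarray) -> np.ndarray:
    """Strip the model's orthogonal variation from new (centered) rows."""
    Xd = Xnew.copy()
    for w_o, p_o in zip(fit["W_o"], fit["P_o"]):
        t_o = Xd @ w_o
        Xd = Xd - np.outer(t_o, p_o)
    return Xd


def _opls_predict_centered(fit: dict, Xnew: np.ndarray) -> np.ndarray:
    Xd = _opls_filter(fit, Xnew)
    return fit["b"] * (Xd @ fit["w"])


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class OplsModel:
    """A fitted O-PLS model on named features.

    Attributes
    ----------
    feature_ids
        Feature order all weight/loading vectors refer to.
    weights, loadings, scores, coef
        Predictive component: unit-norm weight vector w, loading p,
        training scores t, inner regression coefficient b.
    ortho_weights, ortho_loadings, ortho_scores
        Stacked orthogonal components (K x p, K x p, n x K).
    scaling
        Feature scaling learned on the training matrix; ``predict``
        accepts raw-scale data and applies it.
    y_mean, y_std
        Response centering/scaling; by default the response is centered
        only (y_std = 1).
    stats
        R2Y, Q2Y at the retained structure, Q2Y per candidate count, and
        the fractions of X-variance captured by the predictive and
        orthogonal parts.
    """

    feature_ids: list[str]
    weights: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    coef: float
    ortho_weights: np.ndarray
    ortho_loadings: np.ndarray
    ortho_scores: np.ndarray
    scaling: ScalingParams
    y_mean: float
    y_std: float
    sample_ids: list[str] = field(default_factory=list)
    stats: dict = field(default_factory=dict)
    cv_config: dict = field(default_factory=dict)
    #: residual column means of the training matrix after scaling; nonzero
    #: when the scaling was learned on a superset of the training samples
    x_center: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.x_center is None:
            self.x_center = np.zeros(len(self.feature_ids))

    @property
    def n_orthogonal(self) -> int:
        return self.ortho_weights.shape[0]

    def _fit_dict(self) -> dict:
        return {
            "w": self.weights, "p": self.loadings, "t": self.scores,
            "b": self.coef, "W_o": self.ortho_weights,
            "P_o": self.ortho_loadings, "T_o": self.ortho_scores,
        }

    def _scale_new(self, x: FeatureMatrix) -> np.ndarray:
        missing = [f for f in self.feature_ids if f not in x.values.columns]
        if missing:
            raise ModelError(f"features absent from input: {missing}")
        scaled = self.scaling.transform(x.values)
        return scaled.loc[:, self.feature_ids].to_numpy(dtype=float) - self.x_center

    def coefficient_vector(self) -> pd.Series:
        """Net linear coefficients beta with yhat = y_mean + y_std * (x_scaled @ beta).

        The orthogonal filtering and predictive projection compose to a
        single linear map, so the whole model collapses to one coefficient
        vector on the scaled feature space. Useful for auditing
        perturbation deltas.
        """
        p = len(self.feature_ids)
        M = np.eye(p)
        for w_o, p_o in zip(self.ortho_weights, self.ortho_loadings):
            M = M @ (np.eye(p) - np.outer(w_o, p_o))
        beta = self.coef * (M @ self.weights)
        return pd.Series(beta, index=self.feature_ids, name="coef")

    # -- persistence --------------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "feature_ids": self.feature_ids,
            "sample_ids": self.sample_ids,
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "scores": self.scores.tolist(),
            "coef": self.coef,
            "ortho_weights": self.ortho_weights.tolist(),
            "ortho_loadings": self.ortho_loadings.tolist(),
            "ortho_scores": self.ortho_scores.tolist(),
            "scaling": {
                "mean": self.scaling.mean.tolist(),
                "std": self.scaling.std.tolist(),
                "dropped_features": self.scaling.dropped_features,
            },
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "x_center": self.x_center.tolist(),
            "stats": self.stats,
            "cv_config": self.cv_config,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "OplsModel":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            doc = json.loads(Path(source).read_text())
        else:
            doc = json.loads(source)
        p = len(doc["feature_ids"])
        scaling = ScalingParams(
            mean=pd.Series(doc["scaling"]["mean"], index=doc["feature_ids"]),
            std=pd.Series(doc["scaling"]["std"], index=doc["feature_ids"]),
            dropped_features=list(doc["scaling"]["dropped_features"]),
        )
        return cls(
            feature_ids=list(doc["feature_ids"]),
            sample_ids=list(doc.get("sample_ids", [])),
            weights=np.asarray(doc["weights"], dtype=float),
            loadings=np.asarray(doc["loadings"], dtype=float),
            scores=np.asarray(doc["scores"], dtype=float),
            coef=float(doc["coef"]),
            ortho_weights=np.asarray(doc["ortho_weights"], dtype=float).reshape(-1, p),
            ortho_loadings=np.asarray(doc["ortho_loadings"], dtype=float).reshape(-1, p),
            ortho_scores=np.asarray(doc["ortho_scores"], dtype=float).reshape(
                len(doc["scores"]), -1
            ),
            scaling=scaling,
            y_mean=float(doc["y_mean"]),
            y_std=float(doc["y_std"]),
            x_center=np.asarray(doc.get("x_center", [0.0] * p), dtype=float),
            stats=dict(doc["stats"]),
            cv_config=dict(doc["cv_config"]),
        )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def fit_pls1(x: FeatureMatrix, y: ResponseVector, n_components: int = 1) -> dict:
    """Plain NIPALS PLS1 on an autoscaled matrix; internal reference model.

    Serves as the zero-orthogonal-component limit of O-PLS and as the
    dense-regression baseline in algebraic checks. Returns the raw
    component dictionary plus centering info.
    """
    if n_components < 1:
        raise ModelError("n_components must be >= 1")
    X = x.values.loc[y.sample_ids].to_numpy(dtype=float)
    yv = y.auc.to_numpy(dtype=float)
    x_mean = X.mean(axis=0)
    y_mean = yv.mean()
    fit = _nipals_pls1(X - x_mean, yv - y_mean, n_components)
    fit["x_mean"] = x_mean
    fit["y_mean"] = y_mean
    fit["feature_ids"] = x.feature_ids
    return fit


def pls1_predict(fit: dict, x: FeatureMatrix) -> pd.Series:
    X = x.values.loc[:, fit["feature_ids"]].to_numpy(dtype=float)
    return pd.Series(
        fit["y_mean"] + _pls1_predict(fit, X - fit["x_mean"]),
        index=x.values.index, name="predicted",
    )


def _fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [order[i::folds] for i in range(folds)]


def cross_validate_q2(
    x: FeatureMatrix,
    y: ResponseVector,
    n_orthogonal: int = 0,
    folds: int = 7,
    seed: int = 0,
) -> float:
    """Q2Y = 1 - PRESS/TSS under seeded k-fold CV, refitting per fold.

    The full component structure (predictive + ``n_orthogonal``
    orthogonal components) is refitted on each training fold; PRESS
    accumulates squared out-of-fold errors. Q2Y may be negative.
    """
    X = x.values.loc[y.sample_ids].to_numpy(dtype=float)
    yv = y.auc.to_numpy(dtype=float)
    n = len(yv)
    if folds > n:
        raise ModelError(f"folds={folds} exceeds n={n}")
    press = 0.0
    for test_idx in _fold_indices(n, folds, seed):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if len(train_idx) < 2:
            raise ModelError("a CV fold has fewer than 2 training samples")
        Xtr, ytr = X[train_idx], yv[train_idx]
        mu_x, mu_y = Xtr.mean(axis=0), ytr.mean()
        fit = _fit_opls_arrays(Xtr - mu_x, ytr - mu_y, n_orthogonal)
        yhat = mu_y + _opls_predict_centered(fit, X[test_idx] - mu_x)
        press += float(np.sum((yhat - yv[test_idx]) ** 2))
    tss = float(np.sum((yv - yv.mean()) ** 2))
    return 1.0 - press / tss


def fit_opls(
    x: FeatureMatrix,
    y: ResponseVector,
    max_orthogonal: int = 5,
    folds: int = 7,
    delta_q2: float = 0.05,
    seed: int = 0,
    scaling: ScalingParams | None = None,
) -> OplsModel:
    """Fit O-PLS with sequential, Q2-gated orthogonal component selection.

    ``x`` must already be autoscaled (pass the matching
    :class:`ScalingParams` so the model can consume raw data later; an
    identity scaling is synthesised otherwise). One predictive component
    is always kept. Orthogonal components are added one at a time and the
    K-th is retained iff Q2Y(K) - Q2Y(K-1) > ``delta_q2``; selection
    stops at the first failure.
    """
    xs = x.subset_samples(y.sample_ids)
    X = xs.values.to_numpy(dtype=float)
    yv = y.auc.to_numpy(dtype=float)
    n = len(yv)
    if n < folds:
        raise ModelError(f"need at least folds={folds} samples, got {n}")
    # re-center on the training rows: scaling may come from a superset
    x_center = X.mean(axis=0)
    X = X - x_center

    q2_path = [cross_validate_q2(xs, y, 0, folds, seed)]
    n_ortho = 0
    for k in range(1, max_orthogonal + 1):
        q2_k = cross_validate_q2(xs, y, k, folds, seed)
        q2_path.append(q2_k)
        if q2_k - q2_path[n_ortho] > delta_q2:
            n_ortho = k
        else:
            break

    y_mean = yv.mean()
    fit = _fit_opls_arrays(X, yv - y_mean, n_ortho)
    yhat = y_mean + _opls_predict_centered(fit, X)
    tss = float(np.sum((yv - y_mean) ** 2))
    r2y = 1.0 - float(np.sum((yhat - yv) ** 2)) / tss
    ssx = float(np.sum(X ** 2))
    r2x_pred = float(np.sum(np.outer(fit["t"], fit["p"]) ** 2)) / ssx
    r2x_orth = float(
        sum(
            np.sum(np.outer(fit["T_o"][:, k], fit["P_o"][k]) ** 2)
            for k in range(fit["W_o"].shape[0])
        )
    ) / ssx

    if scaling is None:
        scaling = ScalingParams(
            mean=pd.Series(0.0, index=xs.feature_ids),
            std=pd.Series(1.0, index=xs.feature_ids),
        )
    return OplsModel(
        feature_ids=xs.feature_ids,
        sample_ids=y.sample_ids,
        weights=fit["w"],
        loadings=fit["p"],
        scores=fit["t"],
        coef=float(fit["b"]),
        ortho_weights=fit["W_o"],
        ortho_loadings=fit["P_o"],
        ortho_scores=fit["T_o"],
        scaling=scaling,
        y_mean=float(y_mean),
        y_std=1.0,
        x_center=x_center,
        stats={
            "R2Y": r2y,
            "Q2Y": q2_path[n_ortho],
            "Q2Y_path": q2_path,
            "R2X_pred": r2x_pred,
            "R2X_orthog": r2x_orth,
            "n_orthogonal": n_ortho,
        },
        cv_config={"folds": folds, "delta_q2": delta_q2, "seed": seed},
    )


def predict(model: OplsModel, x_new: FeatureMatrix) -> pd.Series:
    """Predict the response for new raw-scale samples.

    The model's stored scaling is applied, orthogonal variation is
    stripped with the stored orthogonal loadings, and the projection on
    the predictive component is mapped back to the original response
    scale.
    """
    Xs = model._scale_new(x_new)
    yhat = model.y_mean + model.y_std * _opls_predict_centered(model._fit_dict(), Xs)
    return pd.Series(yhat, index=x_new.values.index, name="predicted")


def scores_projection(model: OplsModel, x: FeatureMatrix):
    """Predictive and orthogonal score coordinates for new samples.

    Returns a DataFrame with column ``t`` and one ``t_o{k}`` column per
    orthogonal component; the scores of the training matrix reproduce the
    stored training scores.
    """
    Xs = model._scale_new(x)
    fit = model._fit_dict()
    cols = {}
    Xd = Xs.copy()
    for k, (w_o, p_o) in enumerate(zip(fit["W_o"], fit["P_o"]), start=1):
        t_o = Xd @ w_o
        cols[f"t_o{k}"] = t_o
        Xd = Xd - np.outer(t_o, p_o)
    out = {"t": Xd @ fit["w"]}
    out.update(cols)
    return pd.DataFrame(out, index=x.values.index)


def compute_vip(model: OplsModel) -> pd.DataFrame:
    """Per-feature VIP score and signed predictive weight.

    SS_m is the fraction of (centered) training-y variance explained by
    regressing y on component m's scores; orthogonal components
    contribute exactly zero because their scores are uncorrelated with y.
    The ``important`` flag marks VIP > 1.
    """
    # SS_m = b_m^2 t_m't_m / y'y; VIP only uses SS ratios so the common
    # 1/y'y factor cancels and need not be stored.
    comps = [(model.weights, model.scores, model.coef)]
    for k in range(model.n_orthogonal):
        t_o = model.ortho_scores[:, k]
        # inner coefficient of y on t_o is 0 by construction
        comps.append((model.ortho_weights[k], t_o, 0.0))
    ss = np.array([b * b * float(t @ t) for _, t, b in comps])
    if ss.sum() <= 0:
        raise ModelError("model explains no response variance")
    W = np.stack([w for w, _, _ in comps])  # M x p
    p = W.shape[1]
    vip = np.sqrt(p * (W ** 2 * ss[:, None]).sum(axis=0) / ss.sum())
    return pd.DataFrame(
        {
            "VIP": vip,
            "weight": model.weights,
            "important": vip > 1.0,
        },
        index=pd.Index(model.feature_ids, name="feature_id"),
    )
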