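"""Protein signature extraction and univariate correlation comparison.

Features with VIP > 1 form the model's signature; the sign of the
predictive weight splits it into a resistance-associated side (negative
weight: high abundance projects toward low sensitivity AUC) and a
sensitivity-associated side (positive weight). Univariate ordinary
least-squares R^2 of the response on single features lets the signature
be compared layer-by-layer (transcript vs total protein vs
phosphoprotein) for matched gene/protein groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FeatureMatrix, ResponseVector

log = logging.getLogger(__name__)

LAYERS = ("transcript", "total", "phospho")


class SignatureError(ValueError):
    pass


def select_signature(vip: pd.DataFrame) -> pd.DataFrame:
    """Extract the VIP > 1 signature, ordered by |weight| descending.

    Expects the VIP table produced by :func:`basketpls.opls.compute_vip`
    (columns ``VIP`` and ``weight``). Adds a ``direction`` column:
    ``resistance`` for negative predictive weights, ``sensitivity`` for
    positive. An empty signature is allowed and logged.
    """
    if not {"VIP", "weight"}.issubset(vip.columns):
        raise SignatureError("VIP table needs 'VIP' and 'weight' columns")
    sig = vip.loc[vip["VIP"] > 1.0, ["VIP", "weight"]].copy()
    if sig.empty:
        log.warning("no feature exceeds VIP 1; signature is empty")
    sig["direction"] = np.where(sig["weight"] < 0, "resistance", "sensitivity")
    return sig.sort_values("weight", key=np.abs, ascending=False)


@dataclass
class CorrelationRecord:
    """Univariate OLS fit of the response on a single feature."""

    feature_id: str
    layer: str
    r_squared: float
    slope_sign: int
    n: int


def univariate_correlation(
    values: pd.Series, y: ResponseVector, layer: str = "total"
) -> CorrelationRecord:
    """OLS R^2 and slope sign of the response against one feature.

    Pairs are matched by sample id; missing measurements are dropped.
    Needs at least 3 paired observations and a non-constant feature.
    """
    common = [s for s in y.sample_ids if s in values.index]
    v = values.loc[common].astype(float)
    keep = v.notna()
    v = v[keep]
    resp = y.auc.loc[v.index]
    if len(v) < 3:
        raise SignatureError(
            f"need >= 3 paired observations for {values.name!r}, got {len(v)}"
        )
    if np.ptp(v.to_numpy()) == 0:
        raise SignatureError(f"feature {values.name!r} is constant")
    res = stats.linregress(v.to_numpy(), resp.to_numpy())
    return CorrelationRecord(
        feature_id=str(values.name),
        layer=layer,
        r_squared=float(res.rvalue**2),
        slope_sign=int(np.sign(res.slope)),
        n=len(v),
    )


def read_layer_mapping(path, sep="\t") -> pd.DataFrame:
    """Read the gene/total/phospho mapping table (empty cells allowed)."""
    m = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    needed = {"gene_id", "total_feature_id", "phospho_feature_id"}
    if not needed.issubset(m.columns):
        raise SignatureError(f"mapping file needs columns {sorted(needed)}")
    return m.replace("", pd.NA)


def correlation_table(
    mapping: pd.DataFrame,
    layers: dict[str, FeatureMatrix],
    y: ResponseVector,
) -> pd.DataFrame:
    """Univariate R^2 per layer for each matched gene/protein group.

    ``mapping`` rows give (gene_id, total_feature_id, phospho_feature_id);
    ``layers`` maps layer name (``transcript``, ``total``, ``phospho``) to
    the matrix carrying that layer. Unresolvable features are skipped with
    a log entry; a group with no resolvable feature in any layer raises.
    Returns a long-format DataFrame with a ``best_layer`` annotation per
    group (layer with the highest R^2).
    """
    col_of = {
        "transcript": "gene_id",
        "total": "total_feature_id",
        "phospho": "phospho_feature_id",
    }
    records = []
    for _, row in mapping.iterrows():
        group = row["gene_id"] if pd.notna(row["gene_id"]) else row["total_feature_id"]
        group_records = []
        for layer in LAYERS:
            fid = row[col_of[layer]]
            if pd.isna(fid):
                continue
            mat = layers.get(layer)
            if mat is None or fid not in mat.values.columns:
                log.info("group %s: feature %r not resolvable in layer %s",
                         group, fid, layer)
                continue
            rec = univariate_correlation(mat.values[fid], y, layer=layer)
            group_records.append(rec)
        if not group_records:
            raise SignatureError(f"group {group!r}: no resolvable feature in any layer")
        best = max(group_records, key=lambda r: r.r_squared)
        for rec in group_records:
            records.append(
                {
                    "group": group,
                    "layer": rec.layer,
                    "feature_id": rec.feature_id,
                    "r_squared": rec.r_squared,
                    "slope_sign": rec.slope_sign,
                    "n": rec.n,
                    "best_layer": best.layer,
                }
            )
    return pd.DataFrame(records)
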