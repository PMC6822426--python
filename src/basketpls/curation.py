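"""Reading, aligning, filtering, scaling and splitting of input tables.

Mirrors the curation applied to the pan-cancer RPPA / drug-sensitivity
data before modelling: intersect the abundance matrix with the response
table on cell-line id, keep features detected in at least a minimum
fraction of lines (25% by default), impute the remaining missing values,
autoscale (mean-center, unit variance), and split train/test so every
(tumor-type x resistance) stratum is represented on both sides.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CurationError,
    FeatureMatrix,
    ResponseVector,
    ScalingParams,
    SplitSpec,
)

log = logging.getLogger(__name__)

MISSING_TOKENS = ("", "NA", "NaN", "nan", "N/A", "null")

#: phospho features are conventionally suffixed with the modified residue,
#: e.g. "HER3_pY1289" or "MEK1-pS217"; used only as a fallback when no
#: annotation sidecar is supplied.
_PHOSPHO_RE = re.compile(r"[_\-.]p[YST]\d+", re.IGNORECASE)


def _read_delimited(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CurationError(f"input file not found: {path}")
    sep = kwargs.pop("sep", None)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, **kwargs)


def _infer_kind(feature_id: str) -> str:
    return "phospho" if _PHOSPHO_RE.search(feature_id) else "total"


def read_feature_matrix(path, annotation_path=None, sample_meta_path=None,
                        sep=None) -> FeatureMatrix:
    """Read a delimited samples x features table into a :class:`FeatureMatrix`.

    First column must be ``sample_id``; the header row carries feature ids.
    Empty cells and the token ``NA`` denote missing measurements. Feature
    kind (total/phospho) and receptor flags come from the optional
    annotation sidecar, falling back to an id-suffix convention
    (``"_pY1289"`` and friends imply phospho).
    """
    raw = _read_delimited(path, sep=sep)
    if raw.columns[0] != "sample_id":
        raise CurationError(
            f"first column must be 'sample_id', got {raw.columns[0]!r}"
        )
    raw = raw.set_index("sample_id")
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise CurationError(f"duplicate sample ids: {dups}")
    if raw.columns.duplicated().any():
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise CurationError(f"duplicate feature ids: {dups}")

    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cell = raw[col].str.strip()
        is_missing = cell.isin(MISSING_TOKENS)
        parsed = pd.to_numeric(cell.where(~is_missing), errors="coerce")
        bad = (~is_missing) & parsed.isna()
        if bad.any():
            row = raw.index[bad][0]
            raise CurationError(
                f"non-numeric value {raw.loc[row, col]!r} at sample "
                f"{row!r}, feature {col!r}"
            )
        values[col] = parsed

    feature_meta = None
    if annotation_path is not None:
        ann = _read_delimited(annotation_path)
        ann = ann.set_index(ann.columns[0])
        feature_meta = pd.DataFrame(index=values.columns)
        feature_meta["kind"] = ann["kind"].reindex(values.columns)
        if "is_receptor" in ann.columns:
            flags = ann["is_receptor"].reindex(values.columns)
            feature_meta["is_receptor"] = flags.isin(("1", "true", "True", "yes"))
        else:
            feature_meta["is_receptor"] = False
        inferred = [_infer_kind(f) for f in values.columns]
        feature_meta["kind"] = feature_meta["kind"].fillna(pd.Series(inferred, index=values.columns))
    else:
        feature_meta = pd.DataFrame(
            {
                "kind": [_infer_kind(f) for f in values.columns],
                "is_receptor": False,
            },
            index=values.columns,
        )

    sample_meta = None
    if sample_meta_path is not None:
        sm = _read_delimited(sample_meta_path).set_index("sample_id")
        sample_meta = pd.DataFrame(index=values.index)
        sample_meta["tumor_type"] = sm["tumor_type"].reindex(values.index)

    return FeatureMatrix(values, feature_meta, sample_meta)


def read_response(path, sep=None) -> ResponseVector:
    """Read a (sample_id, auc) delimited table."""
    raw = _read_delimited(path, sep=sep)
    if "sample_id" not in raw.columns or "auc" not in raw.columns:
        raise CurationError("response table needs 'sample_id' and 'auc' columns")
    auc = pd.to_numeric(raw.set_index("sample_id")["auc"], errors="coerce")
    return ResponseVector(auc)


def write_feature_matrix(x: FeatureMatrix, path, sep="\t") -> None:
    out = x.values.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep, na_rep="NA")


def write_response(y: ResponseVector, path, sep="\t") -> None:
    out = y.auc.rename("auc").to_frame()
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep)


def intersect_datasets(x: FeatureMatrix, y: ResponseVector):
    """Restrict matrix and response to their common samples, same order.

    Order follows the matrix's sample order restricted to the overlap.
    """
    common = [s for s in x.sample_ids if s in set(y.sample_ids)]
    if not common:
        raise CurationError("no samples shared between feature matrix and response")
    return x.subset_samples(common), y.subset(common)


def filter_by_detection(x: FeatureMatrix, min_fraction: float = 0.25) -> FeatureMatrix:
    """Keep features detected (non-missing) in >= ``min_fraction`` of samples."""
    if not 0 < min_fraction <= 1:
        raise CurationError("min_fraction must be in (0, 1]")
    frac = x.values.notna().mean(axis=0)
    keep = frac.index[frac >= min_fraction].tolist()
    if not keep:
        raise CurationError("no feature passes the detection filter")
    dropped = x.values.shape[1] - len(keep)
    if dropped:
        log.info("detection filter dropped %d/%d features", dropped, x.values.shape[1])
    return x.subset_features(keep)


def impute_missing(x: FeatureMatrix, strategy="feature_mean", constant=0.0) -> FeatureMatrix:
    """Fill missing entries; ``feature_mean`` or ``constant``.

    Feature-mean imputation before autoscaling is equivalent to imputing
    zero after autoscaling, so missing values are neutral under
    mean-centering either way.
    """
    vals = x.values.copy()
    if strategy == "feature_mean":
        n_obs = vals.notna().sum(axis=0)
        if (n_obs == 0).any():
            bad = n_obs.index[n_obs == 0].tolist()
            raise CurationError(
                f"cannot mean-impute fully-missing features: {bad}"
            )
        vals = vals.fillna(vals.mean(axis=0))
    elif strategy == "constant":
        vals = vals.fillna(float(constant))
    else:
        raise CurationError(f"unknown imputation strategy: {strategy!r}")
    return FeatureMatrix(vals, x.feature_meta.copy(), x.sample_meta.copy())


def autoscale(x: FeatureMatrix):
    """Mean-center and unit-variance scale every feature (n-1 variance).

    Zero-variance features are dropped with a warning and recorded in the
    returned :class:`ScalingParams` so the transform stays invertible on
    the retained set.

    Returns
    -------
    (FeatureMatrix, ScalingParams)
    """
    if x.values.isna().any().any():
        raise CurationError("autoscale requires an imputed (complete) matrix")
    std = x.values.std(axis=0, ddof=1)
    dropped = std.index[std == 0].tolist()
    if dropped:
        log.warning("dropping %d zero-variance features: %s", len(dropped), dropped)
    keep = [f for f in x.feature_ids if f not in set(dropped)]
    sub = x.subset_features(keep)
    params = ScalingParams(
        mean=sub.values.mean(axis=0),
        std=sub.values.std(axis=0, ddof=1),
        dropped_features=dropped,
    )
    scaled = params.transform(sub.values)
    return FeatureMatrix(scaled, sub.feature_meta.copy(), sub.sample_meta.copy()), params


def classify_resistance(y: ResponseVector, threshold: float = 0.2) -> pd.Series:
    """Label samples resistant iff AUC < threshold (strict), else sensitive."""
    return pd.Series(
        np.where(y.auc < threshold, "resistant", "sensitive"),
        index=y.auc.index,
        name="resistance",
    )


def stratified_split(
    x: FeatureMatrix,
    y: ResponseVector,
    test_n: int = 6,
    seed: int = 0,
    resistance_threshold: float = 0.2,
) -> SplitSpec:
    """Random train/test split guaranteeing stratum coverage on both sides.

    Strata are the cross of tumor-type group and resistance label. The
    split is random under ``seed`` but constrained so that each stratum
    contributes at least one sample to the training set and one to the
    test set, mirroring a deliberately balanced (not entirely random)
    design.
    """
    resist = classify_resistance(y, resistance_threshold)
    tumor = x.sample_meta["tumor_type"].reindex(y.auc.index)
    strata = tumor.astype(str) + "|" + resist.astype(str)
    strata.name = "stratum"

    counts = strata.value_counts()
    singletons = counts.index[counts < 2].tolist()
    if singletons:
        raise CurationError(
            f"strata with fewer than 2 members cannot appear in both sets: {singletons}"
        )
    n_strata = counts.size
    if test_n < n_strata:
        raise CurationError(
            f"test_n={test_n} cannot cover all {n_strata} strata"
        )
    n = len(strata)
    if test_n > n - n_strata:
        raise CurationError("test_n leaves too few samples to cover strata in train")

    rng = np.random.default_rng(seed)
    ids = np.array(strata.index)
    test: list[str] = []
    reserved_train: list[str] = []
    for label in sorted(counts.index):
        members = ids[strata.values == label]
        pick = rng.choice(members, size=2, replace=False)
        test.append(pick[0])
        reserved_train.append(pick[1])
    remaining = [s for s in ids if s not in set(test) | set(reserved_train)]
    extra = test_n - n_strata
    if extra > 0:
        test.extend(rng.choice(np.array(remaining), size=extra, replace=False))
    train = [s for s in ids if s not in set(test)]
    return SplitSpec(train_ids=train, test_ids=sorted(test, key=list(ids).index),
                     strata=strata)
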