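"""Core containers shared across the pipeline.

The pipeline moves three kinds of data around: a samples x features
protein (or transcript) abundance matrix with per-feature annotations, a
per-sample drug-sensitivity response (normalized inhibition AUC in
[0, 1]), and the scaling parameters that make a fitted model applicable
to new raw-scale data. All are thin wrappers over pandas objects so that
sample/feature alignment is always done by id, never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_KINDS = ("total", "phospho", "transcript")


class CurationError(ValueError):
    """Raised when an input table violates the pipeline's contracts."""


@dataclass
class FeatureMatrix:
    """Samples x features abundance matrix with feature/sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with feature ids as columns.
        Missing measurements are NaN, never silently zero.
    feature_meta
        DataFrame indexed by feature id with columns ``kind`` (one of
        ``total``, ``phospho``, ``transcript``) and ``is_receptor`` (bool).
    sample_meta
        DataFrame indexed by sample id with a ``tumor_type`` column.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame = None
    sample_meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise CurationError(f"duplicate sample ids: {dups}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise CurationError(f"duplicate feature ids: {dups}")
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(
                {"kind": "total", "is_receptor": False}, index=cols
            )
        else:
            self.feature_meta = self.feature_meta.reindex(cols)
            self.feature_meta["kind"] = self.feature_meta["kind"].fillna("total")
            self.feature_meta["is_receptor"] = (
                self.feature_meta["is_receptor"].fillna(False).astype(bool)
            )
            bad = set(self.feature_meta["kind"]) - set(FEATURE_KINDS)
            if bad:
                raise CurationError(f"unknown feature kind(s): {sorted(bad)}")
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame({"tumor_type": "unknown"}, index=idx)
        else:
            self.sample_meta = self.sample_meta.reindex(idx)
            self.sample_meta["tumor_type"] = self.sample_meta["tumor_type"].fillna(
                "unknown"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, feature_ids) -> "FeatureMatrix":
        missing = [f for f in feature_ids if f not in self.values.columns]
        if missing:
            raise CurationError(f"unknown feature ids: {missing}")
        return FeatureMatrix(
            self.values.loc[:, list(feature_ids)].copy(),
            self.feature_meta.loc[list(feature_ids)].copy(),
            self.sample_meta.copy(),
        )

    def subset_samples(self, sample_ids) -> "FeatureMatrix":
        missing = [s for s in sample_ids if s not in self.values.index]
        if missing:
            raise CurationError(f"unknown sample ids: {missing}")
        return FeatureMatrix(
            self.values.loc[list(sample_ids)].copy(),
            self.feature_meta.copy(),
            self.sample_meta.loc[list(sample_ids)].copy(),
        )


@dataclass
class ResponseVector:
    """Per-sample normalized inhibition AUC, bounded to [0, 1]."""

    auc: pd.Series  # index = sample ids

    def __post_init__(self) -> None:
        if self.auc.index.duplicated().any():
            dups = self.auc.index[self.auc.index.duplicated()].unique().tolist()
            raise CurationError(f"duplicate sample ids in response: {dups}")
        vals = self.auc.to_numpy(dtype=float)
        if np.isnan(vals).any():
            bad = self.auc.index[np.isnan(vals)].tolist()
            raise CurationError(f"missing response for samples: {bad}")
        if (vals < 0).any() or (vals > 1).any():
            bad = self.auc.index[(vals < 0) | (vals > 1)].tolist()
            raise CurationError(f"AUC outside [0, 1] for samples: {bad}")
        self.auc = self.auc.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.auc.index)

    def subset(self, sample_ids) -> "ResponseVector":
        return ResponseVector(self.auc.loc[list(sample_ids)].copy())


@dataclass
class ScalingParams:
    """Per-feature centering/scaling learned by :func:`autoscale`.

    Standard deviations use the n-1 (sample) denominator; features whose
    variance is exactly zero are dropped before scaling and listed in
    ``dropped_features``.
    """

    mean: pd.Series
    std: pd.Series
    dropped_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.std <= 0).any():
            bad = self.std.index[self.std <= 0].tolist()
            raise ValueError(f"non-positive std for features: {bad}")

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        aligned = values.loc[:, self.mean.index]
        return (aligned - self.mean) / self.std

    def inverse_transform(self, values: pd.DataFrame) -> pd.DataFrame:
        return values * self.std + self.mean


@dataclass
class SplitSpec:
    """Train/test sample partition with the stratum label of every sample."""

    train_ids: list[str]
    test_ids: list[str]
    strata: pd.Series  # index = sample ids, values = stratum labels

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)}")
        all_ids = set(self.train_ids) | set(self.test_ids)
        if all_ids != set(self.strata.index):
            raise ValueError("train + test ids must cover all stratified samples")
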