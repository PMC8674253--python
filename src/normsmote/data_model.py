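"""Tabular dataset container, min-max normalization and class partitioning.

The central object is :class:`Dataset`: an ``n x r`` matrix of finite numeric
features plus a binary label vector, with one label designated as the
*minority* (positive) class.  All oversampling and diagnostics in this package
operate on datasets normalized feature-wise to the unit interval,

    x' = (x - x_min) / (x_max - x_min),

with the per-feature minima/maxima recorded in :class:`NormalizationParams` so
the mapping can be inverted exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("normsmote")

__all__ = [
    "Dataset",
    "NormalizationParams",
    "ClassPartition",
    "ValidationError",
    "load_csv",
    "normalize",
    "apply_normalization",
    "denormalize",
    "partition_by_class",
    "imbalance_ratio",
]

#: Missing-value sentinels recognised in CSV input (UCI dialect).
DEFAULT_NA_SENTINELS = ("", "?")


class ValidationError(ValueError):
    """Raised when input data violates a documented precondition."""


@dataclass(frozen=True)
class Dataset:
    """Numeric feature matrix with binary labels and a minority designation.

    Parameters
    ----------
    features : ndarray, shape (n, r)
        Finite numeric feature values.
    labels : ndarray, shape (n,)
        Exactly two distinct label values.
    minority_label : scalar
        The label treated as the positive / minority class.
    feature_names : tuple of str
        Length-r column identifiers.
    """

    features: np.ndarray
    labels: np.ndarray
    minority_label: object
    feature_names: tuple = ()

    def __post_init__(self):
        feats = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels)
        if feats.ndim != 2:
            raise ValidationError("features must be a 2-D matrix")
        n, r = feats.shape
        if n < 2:
            raise ValidationError(f"need at least 2 samples, got {n}")
        if r < 1:
            raise ValidationError("need at least 1 feature")
        if labels.shape != (n,):
            raise ValidationError("labels length must match number of rows")
        if not np.all(np.isfinite(feats)):
            raise ValidationError("features must be finite")
        uniq = set(np.unique(labels).tolist())
        if len(uniq) != 2:
            raise ValidationError(f"exactly two classes required, found {len(uniq)}")
        if self.minority_label not in uniq:
            raise ValidationError(f"minority_label {self.minority_label!r} not present")
        names = tuple(self.feature_names) or tuple(f"f{j}" for j in range(r))
        if len(names) != r:
            raise ValidationError("feature_names length must equal feature count")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_names", names)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def r(self) -> int:
        return self.features.shape[1]

    @property
    def majority_label(self):
        uniq = np.unique(self.labels)
        return uniq[0] if uniq[1] == self.minority_label else uniq[1]

    @property
    def minority_mask(self) -> np.ndarray:
        return self.labels == self.minority_label

    @property
    def n_minority(self) -> int:
        return int(self.minority_mask.sum())

    @property
    def n_majority(self) -> int:
        return self.n - self.n_minority


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature min/max of the fitted data; constant features flagged."""

    mins: np.ndarray
    maxs: np.ndarray
    constant_feature_flags: np.ndarray = field(default=None)

    def __post_init__(self):
        mins = np.asarray(self.mins, dtype=float)
        maxs = np.asarray(self.maxs, dtype=float)
        if mins.shape != maxs.shape or mins.ndim != 1:
            raise ValidationError("mins/maxs must be 1-D vectors of equal length")
        if np.any(mins > maxs):
            raise ValidationError("mins must not exceed maxs")
        flags = mins == maxs
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "maxs", maxs)
        object.__setattr__(self, "constant_feature_flags", flags)

    @property
    def r(self) -> int:
        return self.mins.shape[0]


@dataclass(frozen=True)
class ClassPartition:
    """Row-preserving split of a dataset into its minority and majority parts."""

    minority: np.ndarray
    majority: np.ndarray
    minority_indices: np.ndarray
    majority_indices: np.ndarray


def _auto_minority(labels: np.ndarray):
    """Less frequent label; ties broken by lexicographic order of str form."""
    uniq, counts = np.unique(labels, return_counts=True)
    if counts[0] != counts[1]:
        return uniq[np.argmin(counts)]
    return sorted(uniq, key=str)[0]


def load_csv(
    path,
    label_column: str,
    minority_label=None,
    na_sentinels=DEFAULT_NA_SENTINELS,
) -> Dataset:
    """Load a UCI-style numeric CSV into a :class:`Dataset`.

    Rows containing missing values (empty cells or ``"?"`` by default) are
    dropped and the drop count logged.  Any remaining non-numeric feature
    cell is a parse error.
    """
    na_values = [s for s in na_sentinels if s != ""]
    df = pd.read_csv(path, na_values=na_values, skipinitialspace=True)
    if label_column not in df.columns:
        raise ValidationError(f"label column {label_column!r} not in CSV header")
    n_raw = len(df)
    df = df.dropna()
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.info("dropped %d rows with missing values (%d -> %d)", n_dropped, n_raw, len(df))
    feature_cols = [c for c in df.columns if c != label_column]
    if not feature_cols:
        raise ValidationError("no feature columns besides the label column")
    try:
        feats = df[feature_cols].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric feature cell: {exc}") from exc
    if not np.all(np.isfinite(feats)):
        raise ValidationError("non-finite feature value in CSV")
    labels = df[label_column].to_numpy()
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValidationError(f"expected two classes, found {len(uniq)} in {label_column!r}")
    if minority_label is None:
        minority_label = _auto_minority(labels)
    else:
        # accept a string spelling of a numeric label from config/CLI
        if minority_label not in uniq:
            coerced = {str(u): u for u in uniq}.get(str(minority_label))
            if coerced is None:
                raise ValidationError(f"minority label {minority_label!r} not present")
            minority_label = coerced
    return Dataset(feats, labels, minority_label, tuple(feature_cols))


def normalize(d: Dataset) -> tuple[Dataset, NormalizationParams]:
    """Min-max map every feature to [0, 1]; constant features map to 0."""
    mins = d.features.min(axis=0)
    maxs = d.features.max(axis=0)
    params = NormalizationParams(mins, maxs)
    if params.constant_feature_flags.any():
        warnings.warn(
            f"{int(params.constant_feature_flags.sum())} constant feature(s) mapped to 0",
            stacklevel=2,
        )
    return apply_normalization(d, params), params


def apply_normalization(d: Dataset, params: NormalizationParams) -> Dataset:
    """Map a dataset through an already-fitted min-max transform.

    Used to place held-out data in the normalized space of the training data;
    values may fall outside [0, 1] when the new data exceeds the fitted range.
    """
    if params.r != d.r:
        raise ValidationError("normalization params dimension mismatch")
    span = np.where(params.constant_feature_flags, 1.0, params.maxs - params.mins)
    scaled = (d.features - params.mins) / span
    scaled[:, params.constant_feature_flags] = 0.0
    return Dataset(scaled, d.labels, d.minority_label, d.feature_names)


def denormalize(d: Dataset, params: NormalizationParams) -> Dataset:
    """Inverse min-max map; constant features restore their stored value."""
    if params.r != d.r:
        raise ValidationError("normalization params dimension mismatch")
    span = np.where(params.constant_feature_flags, 0.0, params.maxs - params.mins)
    restored = d.features * span + params.mins
    return Dataset(restored, d.labels, d.minority_label, d.feature_names)


def partition_by_class(d: Dataset) -> ClassPartition:
    """Split feature rows by class, preserving row order within each class."""
    mask = d.minority_mask
    idx = np.arange(d.n)
    return ClassPartition(
        minority=d.features[mask],
        majority=d.features[~mask],
        minority_indices=idx[mask],
        majority_indices=idx[~mask],
    )


def imbalance_ratio(d_or_counts) -> float:
    """Minority count over majority count (1 = balanced).

    Accepts a :class:`Dataset` or an ``(n_minority, n_majority)`` pair.
    """
    if isinstance(d_or_counts, Dataset):
        n_min, n_maj = d_or_counts.n_minority, d_or_counts.n_majority
    else:
        n_min, n_maj = d_or_counts
    if n_maj <= 0:
        raise ValidationError("majority count must be positive")
    return n_min / n_maj
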