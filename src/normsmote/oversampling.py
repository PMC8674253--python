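"""Minority-class oversampling: classic SMOTE and its Normal-distribution variant.

Classic SMOTE synthesises a minority point on the segment between a minority
sample and one of its k nearest minority neighbours,

    p = x_i + u * (x_ij - x_i),   u ~ Uniform[0, 1].

The Normal-distribution variant replaces the neighbour by the minority
centroid and the uniform coefficient by a Gaussian factor centred on 1,

    p[j] = x_i[j] + f_j * (center[j] - x_i[j]),   f_j ~ N(1, s * sigma0[j]),

where ``sigma0`` is the per-feature sample standard deviation of the
normalized minority class and ``s`` the tunable spread scale (canonically 1,
2/3 or 1/3).  Because E[f] = 1, synthetic points concentrate near the
centroid — with s = 1/3 about 99.7% of factors fall within one sigma0 of 1 —
which counteracts the boundary "marginalization" of segment interpolation.
Expansion stops once the minority/majority ratio reaches a target (0.7 by
default) and the synthetic rows are fused with the normalized original data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import (
    Dataset,
    NormalizationParams,
    ValidationError,
    imbalance_ratio,
    normalize,
    partition_by_class,
)

__all__ = [
    "MinorityProfile",
    "NormalSmoteConfig",
    "SmoteConfig",
    "ExpansionResult",
    "minority_center",
    "minority_feature_stds",
    "minority_profile",
    "required_synthetic_count",
    "knn_minority_neighbors",
    "smote_generate",
    "normal_smote_generate",
    "expand",
]


@dataclass(frozen=True)
class MinorityProfile:
    """Centroid and per-feature spread of the normalized minority class."""

    center: np.ndarray   # length-r, in [0, 1]
    stds: np.ndarray     # length-r, >= 0; 0 iff the feature is constant
    n_minority: int


@dataclass(frozen=True)
class SmoteConfig:
    """Classic SMOTE: k nearest neighbours, uniform interpolation."""

    k: int = 5
    seed: int = 0
    target_ratio: float = 0.7

    def __post_init__(self):
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if not 0 < self.target_ratio <= 1:
            raise ValidationError("target_ratio must be in (0, 1]")


@dataclass(frozen=True)
class NormalSmoteConfig:
    """Normal-distribution SMOTE: Gaussian pull toward the minority centroid.

    ``sigma_scale`` multiplies the per-feature minority standard deviations to
    give the spread of the interpolation factor; 1, 2/3 and 1/3 are the
    canonical settings.  ``clip_to_unit`` optionally clamps synthetic values
    into [0, 1] (off by default: clipping would distort the factor's stated
    distribution).
    """

    sigma_scale: float = 1.0
    target_ratio: float = 0.7
    clip_to_unit: bool = False
    seed: int = 0

    def __post_init__(self):
        if not self.sigma_scale > 0:
            raise ValidationError("sigma_scale must be positive")
        if not 0 < self.target_ratio <= 1:
            raise ValidationError("target_ratio must be in (0, 1]")


@dataclass(frozen=True)
class ExpansionResult:
    """Synthetic rows, the fused (normalized) dataset, and run provenance."""

    synthetic: np.ndarray
    fused: Dataset
    params: NormalizationParams
    provenance: dict = field(default_factory=dict)


def minority_center(minority: np.ndarray) -> np.ndarray:
    """Arithmetic per-feature mean of the minority sample matrix."""
    minority = np.asarray(minority, dtype=float)
    if minority.ndim != 2 or minority.shape[0] < 1:
        raise ValidationError("minority matrix must be non-empty and 2-D")
    return minority.mean(axis=0)


def minority_feature_stds(minority: np.ndarray) -> np.ndarray:
    """Per-feature sample standard deviation (n-1 denominator)."""
    minority = np.asarray(minority, dtype=float)
    if minority.ndim != 2 or minority.shape[0] < 2:
        raise ValidationError("need at least 2 minority samples for a std estimate")
    return minority.std(axis=0, ddof=1)


def minority_profile(minority: np.ndarray) -> MinorityProfile:
    return MinorityProfile(
        center=minority_center(minority),
        stds=minority_feature_stds(minority),
        n_minority=int(np.asarray(minority).shape[0]),
    )


def required_synthetic_count(n_min: int, n_maj: int, target_ratio: float) -> int:
    """Minimal number of minority rows to add so the imbalance ratio reaches target.

    Computed in exact rational arithmetic so binary-float targets such as 0.7
    never round a whole-number threshold (0.7 * 500 = 350) the wrong way.
    """
    if n_maj <= 0:
        raise ValidationError("majority count must be positive")
    if n_min < 0:
        raise ValidationError("minority count must be non-negative")
    threshold = Fraction(*float(target_ratio).as_integer_ratio()) * n_maj
    return max(0, math.ceil(threshold) - n_min)


def knn_minority_neighbors(minority: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest minority neighbours of each minority sample.

    Euclidean distance, self excluded, ties broken toward the lower index
    (stable sort on the explicit distance matrix).
    """
    minority = np.asarray(minority, dtype=float)
    n = minority.shape[0]
    if not 1 <= k <= n - 1:
        raise ValidationError(f"k must be in [1, {n - 1}], got {k}")
    dists = cdist(minority, minority)
    np.fill_diagonal(dists, np.inf)
    order = np.argsort(dists, axis=1, kind="stable")
    return order[:, :k]


def _source_schedule(n: int, count: int, rng: np.random.Generator) -> np.ndarray:
    """Cycle a seeded random permutation of source indices until count is met."""
    perm = rng.permutation(n)
    reps = -(-count // n) if count else 0
    return np.tile(perm, max(reps, 1))[:count]


def smote_generate(minority: np.ndarray, cfg: SmoteConfig, count: int) -> np.ndarray:
    """Classic SMOTE: ``count`` uniform interpolations toward random k-neighbours."""
    minority = np.asarray(minority, dtype=float)
    if count < 0:
        raise ValidationError("count must be non-negative")
    r = minority.shape[1]
    if count == 0:
        return np.empty((0, r))
    if minority.shape[0] < 2:
        raise ValidationError("classic SMOTE needs at least 2 minority samples")
    k = min(cfg.k, minority.shape[0] - 1)
    neighbors = knn_minority_neighbors(minority, k)
    rng = np.random.default_rng(cfg.seed)
    sources = _source_schedule(minority.shape[0], count, rng)
    picks = rng.integers(0, k, size=count)
    u = rng.uniform(0.0, 1.0, size=count)
    x_i = minority[sources]
    x_ij = minority[neighbors[sources, picks]]
    return x_i + u[:, None] * (x_ij - x_i)


def normal_smote_generate(
    minority: np.ndarray,
    profile: MinorityProfile,
    cfg: NormalSmoteConfig,
    count: int,
) -> np.ndarray:
    """Gaussian-factor interpolation of ``count`` rows toward the minority centroid.

    Each synthetic row takes a source minority sample (sources cycle a seeded
    random permutation) and moves it toward the centroid with an independent
    per-feature factor f_j ~ N(1, sigma_scale * sigma0[j]).
    """
    minority = np.asarray(minority, dtype=float)
    if count < 0:
        raise ValidationError("count must be non-negative")
    r = minority.shape[1]
    if count == 0:
        return np.empty((0, r))
    if minority.shape[0] < 2:
        raise ValidationError("need at least 2 minority samples")
    if np.all(profile.stds == 0):
        warnings.warn("all minority features constant: synthetic rows equal the center",
                      stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    sources = _source_schedule(minority.shape[0], count, rng)
    f = rng.normal(loc=1.0, scale=cfg.sigma_scale * profile.stds, size=(count, r))
    x_i = minority[sources]
    synthetic = x_i + f * (profile.center - x_i)
    if cfg.clip_to_unit:
        synthetic = np.clip(synthetic, 0.0, 1.0)
    return synthetic


def expand(d: Dataset, method: str, cfg) -> ExpansionResult:
    """Full pipeline: normalize, profile, count, generate, fuse.

    The fused dataset stays in normalized space (classification is run on
    normalized data); use :func:`normsmote.data_model.denormalize` with the
    returned params to map back to original units.
    """
    if method not in ("smote", "normal"):
        raise ValidationError(f"unknown method {method!r}")
    if d.n_minority < 2:
        raise ValidationError("need at least 2 minority samples to expand")
    normalized, params = normalize(d)
    part = partition_by_class(normalized)
    count = required_synthetic_count(d.n_minority, d.n_majority, cfg.target_ratio)
    if method == "normal":
        profile = minority_profile(part.minority)
        synthetic = normal_smote_generate(part.minority, profile, cfg, count)
    else:
        synthetic = smote_generate(part.minority, cfg, count)
    fused_features = np.vstack([normalized.features, synthetic])
    fused_labels = np.concatenate(
        [normalized.labels, np.full(count, d.minority_label, dtype=normalized.labels.dtype)]
    )
    fused = Dataset(fused_features, fused_labels, d.minority_label, d.feature_names)
    prov = {
        "method": method,
        "config": {k: v for k, v in vars(cfg).items()},
        "seed": cfg.seed,
        "n_minority_before": d.n_minority,
        "n_majority": d.n_majority,
        "n_synthetic": count,
        "n_minority_after": d.n_minority + count,
        "ratio_before": imbalance_ratio(d),
        "achieved_ratio": imbalance_ratio(fused),
        "target_ratio": cfg.target_ratio,
    }
    return ExpansionResult(synthetic=synthetic, fused=fused, params=params, provenance=prov)
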