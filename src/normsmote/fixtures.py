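"""Seeded synthetic imbalanced two-class Gaussian datasets.

Generates two isotropic Gaussian clouds at a chosen centroid separation
(expressed in units of the within-class standard deviation) with chosen class
counts, so every property of the oversampling pipeline — centroid
preservation, variance shrinkage, stopping rule, classifier benefit — can be
exercised deterministically without external data.  Count pairs such as
268/500 or 45/149 emulate the shapes of common UCI benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import Dataset, ValidationError

__all__ = ["FixtureSpec", "make_gaussian_imbalanced"]

MINORITY_LABEL = "pos"
MAJORITY_LABEL = "neg"

_EDGE_CASES = (None, "constant_feature", "duplicate_points", "single_minority_pair")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic imbalanced dataset.

    ``separation`` is the Euclidean distance between the class centroids in
    units of ``within_class_std``; 0 makes the classes exchangeable.
    """

    n_minority: int = 45
    n_majority: int = 149
    r: int = 8
    separation: float = 2.0
    within_class_std: float = 1.0
    seed: int = 0
    edge_case: str | None = None

    def __post_init__(self):
        if self.n_minority < 1 or self.n_majority < 1:
            raise ValidationError("class counts must be positive")
        if self.n_minority > self.n_majority:
            raise ValidationError("minority count must not exceed majority count")
        if self.r < 1:
            raise ValidationError("need at least one feature")
        if self.separation < 0:
            raise ValidationError("separation must be non-negative")
        if self.within_class_std <= 0:
            raise ValidationError("within_class_std must be positive")
        if self.edge_case not in _EDGE_CASES:
            raise ValidationError(f"unknown edge_case {self.edge_case!r}")


def make_gaussian_imbalanced(spec: FixtureSpec) -> Dataset:
    """Draw the two Gaussian clouds described by ``spec`` (deterministic per seed).

    The majority centroid sits at the origin; the minority centroid is offset
    equally along every axis so its Euclidean distance from the origin is
    ``separation * within_class_std``.
    """
    n_min = 2 if spec.edge_case == "single_minority_pair" else spec.n_minority
    rng = np.random.default_rng(spec.seed)
    offset = spec.separation * spec.within_class_std / np.sqrt(spec.r)
    X_maj = rng.normal(0.0, spec.within_class_std, size=(spec.n_majority, spec.r))
    X_min = rng.normal(offset, spec.within_class_std, size=(n_min, spec.r))
    X = np.vstack([X_maj, X_min])
    y = np.array([MAJORITY_LABEL] * spec.n_majority + [MINORITY_LABEL] * n_min)
    if spec.edge_case == "constant_feature":
        X[:, 0] = 5.0
    elif spec.edge_case == "duplicate_points":
        if n_min >= 2:
            X[spec.n_majority + 1] = X[spec.n_majority]
    return Dataset(X, y, MINORITY_LABEL)
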