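"""Confusion-matrix indices for imbalanced binary classification.

Conventions: the minority class is "positive".  ``accuracy_auc`` is overall
accuracy (TP+TN)/total — kept under the name the source literature uses for
it, with ``accuracy`` as an alias; it is NOT area under the ROC curve.
F-value is the beta-weighted harmonic mean of precision and sensitivity;
G-value the geometric mean of sensitivity and specificity.  Ratios with a
zero denominator return 0 with a warning (standard degenerate-fold handling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import ValidationError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "accuracy_auc",
    "accuracy",
    "sensitivity",
    "precision",
    "specificity",
    "f_value",
    "g_value",
    "oob_error",
    "metrics_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValidationError("confusion matrix must be non-empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """The four indices reported for each classification run."""

    accuracy_auc: float
    f_value: float
    g_value: float
    oob_error: float
    beta: float = 1.0

    def to_dict(self) -> dict:
        return {
            "accuracy_auc": self.accuracy_auc,
            "f_value": self.f_value,
            "g_value": self.g_value,
            "oob_error": self.oob_error,
            "beta": self.beta,
        }


def confusion_matrix(y_true, y_pred, minority_label) -> ConfusionMatrix:
    """Count TP/FN/FP/TN with the minority class as positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred length mismatch")
    known = set(np.unique(y_true).tolist()) | set(np.unique(y_pred).tolist())
    # a degenerate fold may lack the minority class entirely; only a third
    # label value is an error
    if len(known - {minority_label}) > 1:
        raise ValidationError(f"unknown label values: {sorted(map(str, known))}")
    pos_t = y_true == minority_label
    pos_p = y_pred == minority_label
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); returning 0", stacklevel=3)
        return 0.0
    return num / den


def accuracy_auc(cm: ConfusionMatrix) -> float:
    """(TP + TN) / total — overall accuracy."""
    return (cm.tp + cm.tn) / cm.total


accuracy = accuracy_auc


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN): recall on the minority (positive) class."""
    return _safe_ratio(cm.tp, cm.tp + cm.fn, "sensitivity")


def precision(cm: ConfusionMatrix) -> float:
    """TP / (TP + FP)."""
    return _safe_ratio(cm.tp, cm.tp + cm.fp, "precision")


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (FP + TN): recall on the majority (negative) class."""
    return _safe_ratio(cm.tn, cm.fp + cm.tn, "specificity")


def f_value(cm: ConfusionMatrix, beta: float = 1.0) -> float:
    """Beta-weighted harmonic mean of sensitivity and precision."""
    if not 0 < beta <= 1:
        raise ValidationError("beta must be in (0, 1]")
    sens = sensitivity(cm)
    prec = precision(cm)
    denom = beta**2 * sens + prec
    if denom == 0:
        return 0.0
    return (1 + beta**2) * sens * prec / denom


def g_value(cm: ConfusionMatrix) -> float:
    """Geometric mean of sensitivity and specificity (G-mean)."""
    return float(np.sqrt(sensitivity(cm) * specificity(cm)))


def oob_error(per_tree_errors) -> float:
    """Arithmetic mean of per-tree out-of-bag error rates.

    This is the literal tree-wise average, not the conventional
    aggregated-vote OOB error (exposed as ``oob_error_vote`` by the
    evaluation harness).
    """
    errs = np.asarray(per_tree_errors, dtype=float)
    if errs.ndim != 1 or errs.size == 0:
        raise ValidationError("need a non-empty 1-D vector of per-tree errors")
    return float(errs.mean())


def metrics_report(cm: ConfusionMatrix, oob: float = float("nan"), beta: float = 1.0) -> MetricsReport:
    return MetricsReport(
        accuracy_auc=accuracy_auc(cm),
        f_value=f_value(cm, beta),
        g_value=g_value(cm),
        oob_error=oob,
        beta=beta,
    )
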