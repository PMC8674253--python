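"""Random-forest evaluation harness for oversampling experiments.

Protocol: the dataset is split 3:1 by stratified random sampling; a random
forest (Gini splitting, ``floor(log2 r) + 1`` candidate features per split,
bootstrap resampling) is evaluated with stratified k-fold cross-validation on
the training portion, and the fold-level metrics are averaged.  An expansion
experiment repeats expand-and-evaluate several times with derived seeds and
averages the reports.

Leakage modes: ``"fold_safe"`` (default) applies oversampling inside each
training fold only, so no synthetic point is derived from validation rows;
``"paper"`` expands the training portion once before cross-validation, which
reproduces the simpler historical protocol but lets synthetic copies of
fold-validation points leak into fold-training sets.

The out-of-bag (OOB) error reported is the arithmetic mean over trees of each
tree's error on the bootstrap samples it did not see; the conventional
aggregated-vote OOB error is available separately as :func:`oob_error_vote`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble import _forest as _sk_forest
from sklearn.model_selection import StratifiedKFold, train_test_split

from .data_model import Dataset, ValidationError, apply_normalization
from .metrics import MetricsReport, confusion_matrix, metrics_report, oob_error
from .oversampling import expand

__all__ = [
    "EvalProtocol",
    "EvalResult",
    "features_per_split",
    "stratified_split",
    "per_tree_oob_errors",
    "oob_error_vote",
    "run_cv_random_forest",
    "evaluate_expansion",
]


@dataclass(frozen=True)
class EvalProtocol:
    test_fraction: float = 0.25
    cv_folds: int = 5
    expansion_repeats: int = 5
    ntree: int = 100
    feature_subset_rule: str = "log2r_plus_1"
    leakage_mode: str = "fold_safe"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValidationError("test_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.expansion_repeats < 1:
            raise ValidationError("expansion_repeats must be >= 1")
        if self.ntree < 1:
            raise ValidationError("ntree must be >= 1")
        if self.leakage_mode not in ("fold_safe", "paper"):
            raise ValidationError(f"unknown leakage_mode {self.leakage_mode!r}")


@dataclass(frozen=True)
class EvalResult:
    per_repeat: tuple
    mean: MetricsReport
    protocol: EvalProtocol
    seeds: tuple = field(default_factory=tuple)


def features_per_split(r: int) -> int:
    """Candidate features per split: floor(log2 r) + 1, capped at r."""
    if r < 1:
        raise ValidationError("need at least one feature")
    return min(r, int(np.floor(np.log2(r))) + 1)


def stratified_split(d: Dataset, test_fraction: float, seed: int) -> tuple[Dataset, Dataset]:
    """Stratified random train/test split preserving class proportions."""
    counts = [d.n_minority, d.n_majority]
    if min(counts) < 2:
        raise ValidationError("each class needs >= 2 samples to stratify")
    idx_train, idx_test = train_test_split(
        np.arange(d.n),
        test_size=test_fraction,
        stratify=d.labels,
        random_state=seed,
    )
    mk = lambda idx: Dataset(
        d.features[idx], d.labels[idx], d.minority_label, d.feature_names
    )
    return mk(np.sort(idx_train)), mk(np.sort(idx_test))


def _fit_forest(X, y, ntree, h, seed) -> RandomForestClassifier:
    rf = RandomForestClassifier(
        n_estimators=ntree,
        criterion="gini",
        max_features=h,
        bootstrap=True,
        random_state=seed,
    )
    rf.fit(X, y)
    return rf


def _n_samples_bootstrap(n: int, max_samples) -> int:
    # sklearn >= 1.9 takes a sample_weight argument; earlier versions do not
    try:
        return _sk_forest._get_n_samples_bootstrap(n, max_samples, None)
    except TypeError:
        return _sk_forest._get_n_samples_bootstrap(n, max_samples)


def _unsampled_indices(tree_random_state, n: int, n_boot: int) -> np.ndarray:
    try:
        return _sk_forest._generate_unsampled_indices(tree_random_state, n, n_boot, None)
    except TypeError:
        return _sk_forest._generate_unsampled_indices(tree_random_state, n, n_boot)


def per_tree_oob_errors(rf: RandomForestClassifier, X, y) -> np.ndarray:
    """Each tree's misclassification rate on its own out-of-bag samples."""
    X = np.asarray(X)
    y = np.asarray(y)
    n = X.shape[0]
    n_boot = _n_samples_bootstrap(n, rf.max_samples)
    y_enc = np.searchsorted(rf.classes_, y)
    errs = []
    for tree in rf.estimators_:
        oob_idx = _unsampled_indices(tree.random_state, n, n_boot)
        if oob_idx.size == 0:
            continue
        pred = tree.predict(X[oob_idx])
        errs.append(float(np.mean(pred != y_enc[oob_idx])))
    if not errs:
        raise ValidationError("no tree had out-of-bag samples")
    return np.asarray(errs)


def oob_error_vote(rf: RandomForestClassifier, X, y) -> float:
    """Conventional OOB error: each sample classified by majority vote of the
    trees that did not see it; samples never out-of-bag are skipped."""
    X = np.asarray(X)
    y = np.asarray(y)
    n = X.shape[0]
    n_boot = _n_samples_bootstrap(n, rf.max_samples)
    k = len(rf.classes_)
    votes = np.zeros((n, k), dtype=int)
    for tree in rf.estimators_:
        oob_idx = _unsampled_indices(tree.random_state, n, n_boot)
        if oob_idx.size == 0:
            continue
        pred = tree.predict(X[oob_idx]).astype(int)
        votes[oob_idx, pred] += 1
    seen = votes.sum(axis=1) > 0
    if not seen.any():
        raise ValidationError("no sample was ever out-of-bag")
    y_enc = np.searchsorted(rf.classes_, y)
    return float(np.mean(votes[seen].argmax(axis=1) != y_enc[seen]))


def _mean_report(reports) -> MetricsReport:
    return MetricsReport(
        accuracy_auc=float(np.mean([m.accuracy_auc for m in reports])),
        f_value=float(np.mean([m.f_value for m in reports])),
        g_value=float(np.mean([m.g_value for m in reports])),
        oob_error=float(np.mean([m.oob_error for m in reports])),
        beta=reports[0].beta,
    )


def run_cv_random_forest(train: Dataset, protocol: EvalProtocol, expander=None) -> MetricsReport:
    """Stratified k-fold CV of a random forest; fold metrics averaged.

    ``expander``, if given, maps a fold-training :class:`Dataset` to an
    :class:`~normsmote.oversampling.ExpansionResult`; the fold-validation data
    is then placed in the same normalized space before prediction.
    """
    h = features_per_split(train.r)
    skf = StratifiedKFold(n_splits=protocol.cv_folds, shuffle=True, random_state=protocol.seed)
    fold_reports = []
    for fold, (tr_idx, va_idx) in enumerate(skf.split(train.features, train.labels)):
        fold_train = Dataset(
            train.features[tr_idx], train.labels[tr_idx], train.minority_label, train.feature_names
        )
        X_va = train.features[va_idx]
        if expander is not None:
            result = expander(fold_train)
            fold_train = result.fused
            va_view = Dataset(
                X_va, train.labels[va_idx], train.minority_label, train.feature_names
            )
            X_va = apply_normalization(va_view, result.params).features
        rf = _fit_forest(
            fold_train.features, fold_train.labels, protocol.ntree, h, protocol.seed + fold
        )
        cm = confusion_matrix(train.labels[va_idx], rf.predict(X_va), train.minority_label)
        oob = oob_error(per_tree_oob_errors(rf, fold_train.features, fold_train.labels))
        fold_reports.append(metrics_report(cm, oob=oob))
    return _mean_report(fold_reports)


def _repeat_seeds(master_seed: int, n: int) -> tuple:
    children = np.random.SeedSequence(master_seed).spawn(n)
    return tuple(int(c.generate_state(1)[0] % 2**31) for c in children)


def evaluate_expansion(d: Dataset, method: str, cfg, protocol: EvalProtocol) -> EvalResult:
    """Repeated expand-and-evaluate runs, averaged.

    ``method`` is one of ``"none"``, ``"smote"``, ``"normal"``.  Each repeat
    draws its own derived seed for the 3:1 split, the expansion and the
    forests; per-repeat reports and their arithmetic mean are returned.
    """
    if method not in ("none", "smote", "normal"):
        raise ValidationError(f"unknown method {method!r}")
    seeds = _repeat_seeds(protocol.seed, protocol.expansion_repeats)
    reports = []
    for rep_seed in seeds:
        train, _test = stratified_split(d, protocol.test_fraction, rep_seed)
        rep_protocol = dataclasses.replace(protocol, seed=rep_seed)
        if method == "none":
            reports.append(run_cv_random_forest(train, rep_protocol))
            continue
        rep_cfg = dataclasses.replace(cfg, seed=rep_seed)
        if protocol.leakage_mode == "paper":
            expanded = expand(train, method, rep_cfg)
            reports.append(run_cv_random_forest(expanded.fused, rep_protocol))
        else:
            expander = lambda fold_train: expand(fold_train, method, rep_cfg)
            reports.append(run_cv_random_forest(train, rep_protocol, expander=expander))
    return EvalResult(
        per_repeat=tuple(reports),
        mean=_mean_report(reports),
        protocol=protocol,
        seeds=seeds,
    )
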