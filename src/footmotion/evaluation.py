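"""Confusion accounting, metrics, cross-validation and error profiles.

Per-motion binary results are summarised as TP/TN/FP/FN counts and the
three standard metrics::

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)

Two validation schemes are provided: 10-fold cross-validation (each
observation validated exactly once; per-fold counts pooled so the full
sample contributes to one count table) and a stratified 25% holdout.
Error profiles attribute each classifier's misclassified events to the
true motions they came from, splitting them into the corresponding-motion
share (missed instances of the classifier's own motion) and the
other-motions share (false alarms), which sum to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import MOTIONS, Backend, MotionLabel, train_bank

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "ErrorProfile",
    "metrics",
    "kfold_split",
    "holdout_split",
    "error_profile",
    "crossval_bank",
    "holdout_bank",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        """Binary arrays: 1 = the classifier's motion, 0 = rest."""
        y_true = np.asarray(y_true, int)
        y_pred = np.asarray(y_pred, int)
        return cls(tp=int(((y_true == 1) & (y_pred == 1)).sum()),
                   tn=int(((y_true == 0) & (y_pred == 0)).sum()),
                   fp=int(((y_true == 0) & (y_pred == 1)).sum()),
                   fn=int(((y_true == 1) & (y_pred == 0)).sum()))

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricReport:
    """Accuracy/precision/recall as fractions; a zero-denominator metric
    is None with the corresponding ``undefined_*`` flag set (never a
    silent 0)."""

    accuracy: float
    precision: float | None
    recall: float | None
    undefined_precision: bool = False
    undefined_recall: bool = False


def metrics(c: ConfusionCounts) -> MetricReport:
    if c.total == 0:
        raise ValueError("empty confusion counts")
    acc = (c.tp + c.tn) / c.total
    prec = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    rec = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    return MetricReport(accuracy=acc, precision=prec, recall=rec,
                        undefined_precision=prec is None,
                        undefined_recall=rec is None)


def kfold_split(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Random partition of range(n) into k near-equal folds."""
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def holdout_split(labels, fraction: float = 0.25, seed: int = 0,
                  stratify: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """(train, test) index split; stratified by label by default so every
    motion keeps its proportion within +/-1 sample."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    labels = np.asarray([MotionLabel(l).value for l in labels])
    n = labels.size
    rng = np.random.default_rng(seed)
    if not stratify:
        perm = rng.permutation(n)
        n_test = int(round(fraction * n))
        return np.sort(perm[n_test:]), np.sort(perm[:n_test])
    test_parts = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        n_test = int(round(fraction * idx.size))
        if n_test == 0 or n_test == idx.size:
            raise ValueError(f"stratum '{lab}' too small for fraction {fraction}")
        test_parts.append(rng.permutation(idx)[:n_test])
    test = np.sort(np.concatenate(test_parts))
    train = np.setdiff1d(np.arange(n), test)
    return train, test


@dataclass(frozen=True)
class ErrorProfile:
    """Misclassified-event attribution for one binary classifier."""

    motion: MotionLabel
    counts_by_true_motion: dict[MotionLabel, int]
    corresponding_motion_error: float  # percent
    other_motions_error: float         # percent
    empty: bool = False


def error_profile(motion: MotionLabel | str,
                  true_labels_of_errors) -> ErrorProfile:
    """Profile one classifier's misclassified events.

    ``true_labels_of_errors`` holds the true motion of every event the
    classifier got wrong (its own motion missed = FN, another motion
    accepted = FP).  The corresponding-motion share is the fraction of
    errors whose true label is the classifier's own motion.
    """
    motion = MotionLabel(motion)
    labels = [MotionLabel(l) for l in true_labels_of_errors]
    counts = {m: 0 for m in MOTIONS}
    for l in labels:
        counts[l] += 1
    total = len(labels)
    if total == 0:
        return ErrorProfile(motion=motion, counts_by_true_motion=counts,
                            corresponding_motion_error=float("nan"),
                            other_motions_error=float("nan"), empty=True)
    corr = 100.0 * counts[motion] / total
    return ErrorProfile(motion=motion, counts_by_true_motion=counts,
                        corresponding_motion_error=corr,
                        other_motions_error=100.0 - corr)


# ---------------------------------------------------------------------------
# Scheme runners: train/evaluate a bank under a CV scheme, returning the
# per-motion pooled counts that the metric tables summarise.


def _binary_counts(bank, X, y) -> dict[MotionLabel, ConfusionCounts]:
    preds = bank.binary_predictions(X)
    y = np.asarray([MotionLabel(l).value for l in y])
    out = {}
    for m in MOTIONS:
        y_bin = (y == m.value).astype(int)
        out[m] = ConfusionCounts.from_predictions(y_bin, preds[m])
    return out


def crossval_bank(X, labels, backend: Backend | str = Backend.SVM, k: int = 10,
                  hyperparams: dict | None = None, seed: int = 0,
                  ) -> dict[MotionLabel, ConfusionCounts]:
    """k-fold cross-validation; per-fold counts are pooled so every
    observation contributes to the count table exactly once."""
    X = np.asarray(X, float)
    y = np.asarray([MotionLabel(l).value for l in labels])
    folds = kfold_split(len(y), k, seed)
    pooled = {m: ConfusionCounts(0, 0, 0, 0) for m in MOTIONS}
    for j, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        bank = train_bank(X[train_idx], y[train_idx], backend=backend,
                          hyperparams=hyperparams, seed=seed + j)
        fold_counts = _binary_counts(bank, X[test_idx], y[test_idx])
        pooled = {m: pooled[m] + fold_counts[m] for m in MOTIONS}
    return pooled


def holdout_bank(X, labels, backend: Backend | str = Backend.SVM,
                 fraction: float = 0.25, hyperparams: dict | None = None,
                 seed: int = 0, stratify: bool = True,
                 ) -> dict[MotionLabel, ConfusionCounts]:
    """Stratified holdout validation returning per-motion counts."""
    X = np.asarray(X, float)
    y = np.asarray([MotionLabel(l).value for l in labels])
    train_idx, test_idx = holdout_split(y, fraction=fraction, seed=seed,
                                        stratify=stratify)
    bank = train_bank(X[train_idx], y[train_idx], backend=backend,
                      hyperparams=hyperparams, seed=seed)
    return _binary_counts(bank, X[test_idx], y[test_idx])
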