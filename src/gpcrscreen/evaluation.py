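"""Classifier evaluation: confusion-matrix metrics, ROC/AUC, permutation
test and bootstrap AUC confidence intervals.

The permutation test asks whether the cross-validated accuracy could arise
by chance: labels are shuffled ``n_perm`` times, the full CV is re-run for
each shuffle, and the empirical p-value is the fraction of permutations
reaching the observed accuracy or better.  The bootstrap resamples the
(small) test set with replacement to put a percentile confidence interval
on the AUC; resamples that lose one class entirely are skipped and logged
rather than redrawn, which avoids biasing toward separable resamples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .classifier import HyperParams, cv_accuracy

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "PermutationResult",
    "BootstrapResult",
    "confusion",
    "metrics",
    "precision_recall_f1",
    "roc_auc",
    "roc_points",
    "permutation_test",
    "bootstrap_auc",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionMatrix":
        """The same outcomes viewed with the opposite positive class."""
        return ConfusionMatrix(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float


def confusion(
    predictions: Sequence[int], labels: Sequence[int], positive_class: int = 1
) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with respect to ``positive_class``."""
    pred = np.asarray(predictions)
    y = np.asarray(labels)
    if pred.shape != y.shape:
        raise ValueError(f"length mismatch: {pred.shape} predictions vs {y.shape} labels")
    pos_p = pred == positive_class
    pos_y = y == positive_class
    return ConfusionMatrix(
        tp=int(np.sum(pos_p & pos_y)),
        tn=int(np.sum(~pos_p & ~pos_y)),
        fp=int(np.sum(pos_p & ~pos_y)),
        fn=int(np.sum(~pos_p & pos_y)),
    )


def _ratio(num: int, den: int) -> float:
    """num/den, NaN (undefined) when the denominator is zero."""
    return num / den if den else math.nan


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy (TP+TN)/n, sensitivity TP/(TP+FN), specificity TN/(TN+FP).

    Zero-denominator metrics are reported as NaN (undefined), never as 0.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    return MetricSet(
        accuracy=_ratio(cm.tp + cm.tn, cm.n),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
    )


def precision_recall_f1(cm: ConfusionMatrix) -> tuple[float, float, float]:
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        return precision, recall, math.nan
    return precision, recall, 2 * precision * recall / (precision + recall)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve of `scores` against binary `labels`.

    Equals the Mann–Whitney U statistic / (n_pos * n_neg) with ties
    counted half — i.e. the probability a random positive outscores a
    random negative.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(y, np.asarray(scores, float)))


def roc_points(scores: Sequence[float], labels: Sequence[int]):
    """(fpr, tpr, thresholds) arrays for plotting the ROC curve."""
    return roc_curve(np.asarray(labels), np.asarray(scores, float))


@dataclass(frozen=True)
class PermutationResult:
    observed_accuracy: float
    p_value: float
    n_perm: int
    perm_accuracies: np.ndarray

    @property
    def p_report(self) -> str:
        """Human-readable p; a raw 0 is reported as a bound, not a claim."""
        if self.p_value == 0.0:
            return f"p = 0.00 (< {1.0 / self.n_perm:.4g})"
        return f"p = {self.p_value:.4g}"


def permutation_test(
    matrix,
    labels,
    params: HyperParams,
    n_perm: int = 1000,
    k: int = 5,
    seed: int = 42,
) -> PermutationResult:
    """Label-shuffling significance test of cross-validated accuracy.

    Each permutation re-runs the full stratified k-fold CV on shuffled
    labels at the given hyperparameters; p is the fraction of permuted
    accuracies >= the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(matrix, float)
    y = np.asarray(labels)
    observed = cv_accuracy(X, y, params, k=k, seed=seed)
    rng = np.random.default_rng(seed)
    perm_accs = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        perm_accs[i] = cv_accuracy(X, y_perm, params, k=k, seed=seed)
    p = float(np.mean(perm_accs >= observed))
    return PermutationResult(observed, p, n_perm, perm_accs)


@dataclass(frozen=True)
class BootstrapResult:
    mean_auc: float
    ci_low: float
    ci_high: float
    aucs: np.ndarray
    n_skipped: int


def bootstrap_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 42,
) -> BootstrapResult:
    """Percentile bootstrap CI for the test-set AUC.

    Rows are resampled with replacement `n_boot` times; single-class
    resamples are skipped (logged), keeping the effective count <= n_boot.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    aucs = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(y), size=len(y))
        if len(np.unique(y[idx])) < 2:
            skipped += 1
            continue
        aucs.append(roc_auc(s[idx], y[idx]))
    if skipped:
        logger.info("bootstrap_auc: skipped %d single-class resamples", skipped)
    if not aucs:
        raise ValueError("every bootstrap resample was single-class")
    aucs = np.asarray(aucs)
    alpha = (1 - ci) / 2
    low, high = np.quantile(aucs, [alpha, 1 - alpha])
    return BootstrapResult(float(aucs.mean()), float(low), float(high), aucs, skipped)
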