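"""Diagnostic-classifier evaluation: confusion metrics, ROC/PR, chi-square.

Metrics are derived from TP/FN/FP/TN counts with the positive class being
the infected (FRI = 1) group.  Rate metrics are expressed in percent.
Model-to-model comparisons of a rate use the Pearson chi-square test on
the implied 2x2 table (no continuity correction), with counts recovered
from printed percentages by round-half-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "CurvePoints",
    "confusion_from_predictions",
    "metrics_from_confusion",
    "roc_auc",
    "pr_curve",
    "proportions_to_counts",
    "chi_square_from_counts",
    "chi_square_two_proportions",
    "stratified_kfold",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts, positive class = 1."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Rates in percent (None where the denominator is zero); F1 in [0, 1]."""

    accuracy: float | None
    recall: float | None
    specificity: float | None
    fpr: float | None
    precision: float | None
    f1: float | None


@dataclass(frozen=True)
class CurvePoints:
    x: np.ndarray
    y: np.ndarray
    thresholds: np.ndarray


def _binary(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v)
    if v.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.isin(v, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return v.astype(int)


def confusion_from_predictions(
    truth: np.ndarray, predicted: np.ndarray
) -> ConfusionMatrix:
    truth = _binary(truth, "truth")
    predicted = _binary(predicted, "predicted")
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    return ConfusionMatrix(
        tp=int(np.sum((truth == 1) & (predicted == 1))),
        fn=int(np.sum((truth == 1) & (predicted == 0))),
        fp=int(np.sum((truth == 0) & (predicted == 1))),
        tn=int(np.sum((truth == 0) & (predicted == 0))),
    )


def _rate(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy, recall, specificity, FPR, precision (percent) and F1."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    precision = _rate(cm.tp, cm.tp + cm.fp)
    recall = _rate(cm.tp, cm.tp + cm.fn)
    if precision in (None, 0.0) and recall in (None, 0.0):
        f1 = None
    elif precision is None or recall is None:
        f1 = None
    else:
        p, r = precision / 100.0, recall / 100.0
        f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return MetricSet(
        accuracy=_rate(cm.tp + cm.tn, cm.total),
        recall=recall,
        specificity=_rate(cm.tn, cm.tn + cm.fp),
        fpr=_rate(cm.fp, cm.fp + cm.tn),
        precision=precision,
        f1=f1,
    )


def roc_auc(truth: np.ndarray, scores: np.ndarray) -> tuple[CurvePoints, float]:
    """ROC curve (FPR, TPR) by tie-grouped threshold sweep and trapezoid AUC."""
    truth = _binary(truth, "truth")
    scores = np.asarray(scores, dtype=float)
    if len(set(truth.tolist())) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(truth, scores, drop_intermediate=False)
    return CurvePoints(fpr, tpr, thr), float(_trapezoid_auc(fpr, tpr))


def pr_curve(truth: np.ndarray, scores: np.ndarray) -> CurvePoints:
    """Precision-recall curve with recall non-decreasing along the sweep."""
    truth = _binary(truth, "truth")
    if truth.sum() == 0:
        raise ValueError("positives must be present")
    precision, recall, thr = precision_recall_curve(truth, np.asarray(scores, float))
    # Drop the (recall 0, precision 1) sentinel, order by increasing recall.
    precision, recall = precision[:-1][::-1], recall[:-1][::-1]
    thr = thr[::-1]
    # At a tied recall keep the highest-threshold (best-precision) point so
    # dominated operating points do not sag the curve.
    keep = np.ones(len(recall), dtype=bool)
    keep[1:] = recall[1:] != recall[:-1]
    return CurvePoints(recall[keep], precision[keep], thr[keep])


def proportions_to_counts(p: float, n: int) -> tuple[int, int]:
    """Successes/failures implied by a printed percentage (round half up)."""
    if not 0.0 <= p <= 100.0:
        raise ValueError("p must be a percentage in [0, 100]")
    if n <= 0:
        raise ValueError("n must be positive")
    successes = int(np.floor(p / 100.0 * n + 0.5))
    return successes, n - successes


def chi_square_from_counts(
    a: int, b: int, c: int, d: int
) -> tuple[float, float]:
    """Uncorrected Pearson chi-square for the 2x2 table [[a, b], [c, d]]."""
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("degenerate margins: chi-square undefined")
    chi2 = n * (a * d - b * c) ** 2 / margins
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def chi_square_two_proportions(
    p1: float, p2: float, n1: int, n2: int
) -> tuple[float, float]:
    """Compare two printed percentages at group sizes n1, n2.

    Rebuilds the implied counts by round-half-up and applies the Pearson
    chi-square without continuity correction (1 df).
    """
    a, b = proportions_to_counts(p1, n1)
    c, d = proportions_to_counts(p2, n2)
    return chi_square_from_counts(a, b, c, d)


def stratified_kfold(labels: np.ndarray, folds: int, seed: int = 0) -> np.ndarray:
    """Shuffled stratified fold assignment (one fold id per sample)."""
    labels = _binary(labels, "labels")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < folds:
        raise ValueError("each class must have at least `folds` samples")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment
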