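"""Binary-classification metrics, ROC/AUC, and leave-one-subject-out CV.

Positive class throughout = preictal.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_metrics",
    "relative_accuracy",
    "roc_auc",
    "loocv",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )

    @classmethod
    def from_predictions(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionCounts":
        yt = np.asarray(y_true).astype(int)
        yp = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(((yt == 1) & (yp == 1)).sum()),
            tn=int(((yt == 0) & (yp == 0)).sum()),
            fp=int(((yt == 0) & (yp == 1)).sum()),
            fn=int(((yt == 1) & (yp == 0)).sum()),
        )


@dataclass
class MetricReport:
    sensitivity: float
    specificity: float
    accuracy: float
    fpr: float
    auc: Optional[float] = None
    baseline: Optional[float] = None
    relative_accuracy_pct: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


def confusion_metrics(counts: ConfusionCounts) -> MetricReport:
    """Sensitivity, specificity, accuracy and FPR from a contingency table."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValueError("both classes must be present (nonzero denominators)")
    sens = counts.tp / (counts.tp + counts.fn)
    spec = counts.tn / (counts.tn + counts.fp)
    acc = (counts.tp + counts.tn) / counts.total
    fpr = counts.fp / (counts.fp + counts.tn)
    return MetricReport(sensitivity=sens, specificity=spec, accuracy=acc, fpr=fpr)


def relative_accuracy(accuracy: float, class_counts: Sequence[int]) -> tuple[float, float]:
    """(baseline, relative accuracy %) against the most-frequent-class baseline.

    Relative accuracy is unbounded above and may exceed 100%.
    """
    counts = np.asarray(class_counts, dtype=float)
    if counts.min() <= 0:
        raise ValueError("class counts must be positive")
    baseline = counts.max() / counts.sum()
    return float(baseline), float((accuracy / baseline - 1.0) * 100.0)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, np.ndarray]:
    """AUC via the rank (Mann-Whitney) statistic, ties counted half, plus the
    (FPR, TPR) curve evaluated at every distinct score threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both labels must be present")

    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=float)
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0  # average rank, 1-based
        i = j + 1
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    curve = np.empty((len(thresholds), 2))
    for k, thr in enumerate(thresholds):
        pred = s >= thr
        curve[k, 0] = (pred & (y == 0)).sum() / n_neg
        curve[k, 1] = (pred & (y == 1)).sum() / n_pos
    return float(auc), curve


def loocv(
    subjects: Sequence[str],
    train_fn: Callable[[list[str]], object],
    eval_fn: Callable[[object, str], ConfusionCounts],
    seed: int = 42,
) -> tuple[dict[str, MetricReport], MetricReport]:
    """Leave-one-SUBJECT-out cross-validation.

    For each subject, ``train_fn`` receives the remaining subjects and the
    returned model is scored on the held-out one by ``eval_fn``; fold counts
    are pooled into the aggregate report.
    """
    subjects = list(subjects)
    if len(subjects) < 2:
        raise ValueError("LOOCV needs at least 2 subjects")
    per_subject: dict[str, MetricReport] = {}
    pooled = ConfusionCounts()
    for held_out in subjects:
        train_subjects = [s for s in subjects if s != held_out]
        model = train_fn(train_subjects)
        counts = eval_fn(model, held_out)
        pooled = pooled + counts
        try:
            per_subject[held_out] = confusion_metrics(counts)
        except ValueError:
            acc = (counts.tp + counts.tn) / counts.total if counts.total else float("nan")
            per_subject[held_out] = MetricReport(
                sensitivity=float("nan"), specificity=float("nan"), accuracy=acc, fpr=float("nan")
            )
    return per_subject, confusion_metrics(pooled)
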