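"""Confusion-matrix metrics: balanced accuracy, MCC, sensitivity/specificity.

Balanced accuracy is the mean of the true-positive rate and the
true-negative rate (for K > 2 classes, the unweighted mean of per-class
recalls), which avoids the majority-class bias of simple accuracy under
class imbalance. The Matthews correlation coefficient,

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

requires good performance on both classes; the K-class generalization is
Gorodkin's R_K computed from the full K x K table. A degenerate MCC
denominator returns 0 with a warning, the standard convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "balanced_accuracy", "mcc",
           "sensitivity_specificity", "micro_recall", "summarize_trials"]


@dataclass
class ConfusionMatrix:
    """K x K count table; rows are true classes, columns predicted."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match class_names")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_labels(cls, y_true, y_pred,
                    class_names: tuple[str, ...]) -> "ConfusionMatrix":
        index = {c: i for i, c in enumerate(class_names)}
        counts = np.zeros((len(class_names),) * 2, dtype=np.int64)
        for t, p in zip(y_true, y_pred, strict=True):
            counts[index[t], index[p]] += 1
        return cls(counts, tuple(class_names))

    @classmethod
    def from_binary(cls, tp: int, fn: int, fp: int, tn: int,
                    positive: str = "pos", negative: str = "neg",
                    ) -> "ConfusionMatrix":
        """Binary table with the positive class first."""
        return cls(np.array([[tp, fn], [fp, tn]]), (positive, negative))

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def binary_counts(self, positive_class: str | None = None,
                      ) -> tuple[int, int, int, int]:
        """(TP, FN, FP, TN) with respect to a designated positive class."""
        if self.n_classes != 2 and positive_class is None:
            raise ValueError("positive_class is required for K > 2")
        pos = (self.class_names.index(positive_class)
               if positive_class is not None else 0)
        tp = int(self.counts[pos, pos])
        fn = int(self.counts[pos].sum() - tp)
        fp = int(self.counts[:, pos].sum() - tp)
        tn = int(self.total - tp - fn - fp)
        return tp, fn, fp, tn


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class recalls; for K = 2 this is
    (sensitivity + specificity) / 2."""
    row_sums = cm.counts.sum(axis=1)
    if (row_sums == 0).any():
        empty = [c for c, n in zip(cm.class_names, row_sums) if n == 0]
        raise ValueError(f"no true samples for class(es) {empty}")
    recalls = np.diag(cm.counts) / row_sums
    return float(recalls.mean())


def per_class_recall(cm: ConfusionMatrix) -> dict[str, float]:
    row_sums = cm.counts.sum(axis=1)
    return {c: float(cm.counts[i, i] / row_sums[i]) if row_sums[i] else math.nan
            for i, c in enumerate(cm.class_names)}


def micro_recall(cm: ConfusionMatrix) -> float:
    """Total correct over total evaluated (simple accuracy)."""
    return float(np.diag(cm.counts).sum() / cm.total)


def mcc(cm: ConfusionMatrix, positive_class: str | None = None) -> float:
    """Matthews correlation; binary formula for K = 2, Gorodkin's R_K otherwise."""
    if cm.n_classes == 2:
        tp, fn, fp, tn = cm.binary_counts(positive_class)
        denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        if denom == 0:
            warnings.warn("MCC denominator is zero; returning 0", stacklevel=2)
            return 0.0
        return (tp * tn - fp * fn) / denom
    c = cm.counts.astype(np.float64)
    n = c.sum()
    correct = np.trace(c)
    t = c.sum(axis=1)  # true occurrences
    p = c.sum(axis=0)  # predicted occurrences
    num = correct * n - t @ p
    denom = math.sqrt(n * n - p @ p) * math.sqrt(n * n - t @ t)
    if denom == 0:
        warnings.warn("MCC denominator is zero; returning 0", stacklevel=2)
        return 0.0
    return float(num / denom)


def sensitivity_specificity(cm: ConfusionMatrix,
                            positive_class: str | None = None,
                            ) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP)) for a binary table."""
    tp, fn, fp, tn = cm.binary_counts(positive_class)
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("sensitivity/specificity undefined: empty class")
    return tp / (tp + fn), tn / (tn + fp)


def summarize_trials(per_trial: list[dict[str, float]]) -> pd.DataFrame:
    """Mean and population standard deviation per metric across trials.

    Returns a table with columns mean, sd and a "0.82 ± 0.04"-style
    formatted string, indexed by metric name.
    """
    if not per_trial:
        raise ValueError("need at least one trial")
    df = pd.DataFrame(per_trial)
    mean = df.mean()
    sd = df.std(ddof=0)
    out = pd.DataFrame({"mean": mean, "sd": sd})
    out["formatted"] = [f"{m:.2f} ± {s:.2f}" for m, s in zip(mean, sd)]
    return out
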