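"""Classification performance measures: accuracy and (macro-averaged) F-score.

Conventions for degenerate counts: precision with TP + FP = 0 is taken as 0,
as is recall with TP + FN = 0, so the F-score of a class the classifier
never predicts correctly is 0; classes absent from ``y_true`` are excluded
from the macro average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "accuracy",
    "precision",
    "recall",
    "f_score_one_class",
    "macro_f_score",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check(y_true, y_pred):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("empty input")
    return y_true, y_pred


def confusion_counts(y_true, y_pred, positive_class) -> ConfusionCounts:
    y_true, y_pred = _check(y_true, y_pred)
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def accuracy(y_true, y_pred) -> float:
    """Fraction of samples assigned to the correct class."""
    y_true, y_pred = _check(y_true, y_pred)
    return float(np.mean(y_true == y_pred))


def precision(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else 0.0


def recall(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else 0.0


def f_score_one_class(y_true, y_pred, positive_class) -> float:
    """F-score (harmonic mean of precision and recall) for one class."""
    counts = confusion_counts(y_true, y_pred, positive_class)
    p, r = precision(counts), recall(counts)
    return 2 * p * r / (p + r) if (p + r) else 0.0


def macro_f_score(y_true, y_pred) -> float:
    """Unweighted mean of per-class one-vs-rest F-scores.

    Averaged over the classes present in ``y_true`` (binary data therefore
    averages both one-vs-rest F-scores, not just the positive class's).
    """
    y_true, y_pred = _check(y_true, y_pred)
    classes = np.unique(y_true)
    return float(np.mean([f_score_one_class(y_true, y_pred, c) for c in classes]))
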