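"""Benchmarking of XNA call sets: confusion matrices, recall,
specificity, and ROC/AUC.

Conventions follow the method's own definitions: the positive class is
the XNA; recall = TP/(TP+FN); specificity = 1 - FDR where FDR here
denotes FP/(FP+TN) (the quantity swept against recall to form the ROC).
Note this "FDR" is what the broader literature calls the false-positive
rate; a precision-based variant is available but never the default.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "recall",
    "specificity",
    "precision_based_fdr",
    "roc",
    "RocCurve",
]


@dataclass
class ConfusionMatrix:
    """Counts of (truth base, called base) pairs with a designated
    positive (XNA) class."""

    positive: str
    counts: Counter = field(default_factory=Counter)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, "str | None"]], positive: str) -> "ConfusionMatrix":
        cm = cls(positive=positive)
        for truth, called in pairs:
            cm.counts[(truth, called)] += 1
        return cm

    def add(self, truth: str, called: "str | None", n: int = 1) -> None:
        self.counts[(truth, called)] += n

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def _cell(self, truth_is_pos: bool, called_is_pos: bool) -> int:
        return sum(
            n
            for (truth, called), n in self.counts.items()
            if (truth == self.positive) == truth_is_pos
            and (called == self.positive) == called_is_pos
        )

    @property
    def tp(self) -> int:
        return self._cell(True, True)

    @property
    def fn(self) -> int:
        return self._cell(True, False)

    @property
    def fp(self) -> int:
        return self._cell(False, True)

    @property
    def tn(self) -> int:
        return self._cell(False, False)


def recall(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN): fraction of true XNA positions called as XNA."""
    denom = cm.tp + cm.fn
    if denom == 0:
        raise ValueError("recall undefined: no positive-class observations")
    return cm.tp / denom


def specificity(cm: ConfusionMatrix) -> float:
    """1 - FP/(FP+TN): fraction of XNA-free positions not miscalled as XNA."""
    denom = cm.fp + cm.tn
    if denom == 0:
        raise ValueError("specificity undefined: no negative-class observations")
    return 1.0 - cm.fp / denom


def precision_based_fdr(cm: ConfusionMatrix) -> float:
    """FP / (FP + TP): the literature's usual false-discovery rate.

    Provided for comparison only; never used in ROC construction here.
    """
    denom = cm.fp + cm.tp
    if denom == 0:
        raise ValueError("precision-based FDR undefined: nothing called positive")
    return cm.fp / denom


@dataclass(frozen=True)
class RocCurve:
    """Recall vs FDR (= FP/(FP+TN)) across classification thresholds."""

    fdr: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """ROC from per-observation statistic values and truth labels.

    ``labels`` marks true XNA observations; higher scores must favor the
    XNA hypothesis. Built on scikit-learn's roc_curve/auc with trapezoidal
    integration.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return RocCurve(fdr=fpr, recall=tpr, thresholds=thr, auc=float(_sk_auc(fpr, tpr)))
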