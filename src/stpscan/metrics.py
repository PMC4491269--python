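"""Confusion-matrix statistics and ROC/AUC for binary STP classification.

The positive class is STP. Metrics follow the standard definitions:

    sensitivity = TP / (TP + FN)          specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)          accuracy = (TP + TN) / total
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A zero denominator makes that metric NaN (with a warning) rather than a
silent 0 — MCC in particular is undefined when any margin of the table
is empty. The ROC is a threshold sweep over the unique decision scores
with tied scores grouped into a single step; AUC is the trapezoidal
area under it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.TP + other.TP,
            self.FP + other.FP,
            self.TN + other.TN,
            self.FN + other.FN,
        )


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
        }


def confusion(
    truth: Sequence[int], predicted: Sequence[int]
) -> ConfusionMatrix:
    """2x2 cross-tabulation of binary labels (1 = STP, 0 = non-STP)."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    for arr, name in ((truth, "truth"), (predicted, "predicted")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} labels must be binary 0/1")
    return ConfusionMatrix(
        TP=int(((truth == 1) & (predicted == 1)).sum()),
        FP=int(((truth == 0) & (predicted == 1)).sum()),
        TN=int(((truth == 0) & (predicted == 0)).sum()),
        FN=int(((truth == 1) & (predicted == 0)).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return math.nan
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """The five summary statistics of one confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, tn, fn = cm.TP, cm.FP, cm.TN, cm.FN
    mcc_den2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return MetricSet(
        sensitivity=_ratio(tp, tp + fn, "sensitivity"),
        specificity=_ratio(tn, tn + fp, "specificity"),
        precision=_ratio(tp, tp + fp, "precision"),
        accuracy=(tp + tn) / cm.total,
        mcc=_ratio(tp * tn - fp * fn, math.sqrt(mcc_den2), "mcc"),
    )


def roc_curve(
    scores: Sequence[float], truth: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points from sweeping a threshold over the scores.

    Points are ordered from (0, 0) to (1, 1); equal scores collapse
    into one step so ties cannot inflate the curve.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    P = int((truth == 1).sum())
    N = int((truth == 0).sum())
    if P == 0 or N == 0:
        raise ValueError("ROC needs at least one positive and one negative")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order]
    # cumulative counts at each distinct-score boundary
    tps = np.cumsum(t == 1)
    fps = np.cumsum(t == 0)
    last_of_group = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[last_of_group] / P]
    fpr = np.r_[0.0, fps[last_of_group] / N]
    return fpr, tpr


def auc(scores: Sequence[float], truth: Sequence[int]) -> float:
    """Trapezoidal area under the tie-grouped ROC curve."""
    fpr, tpr = roc_curve(scores, truth)
    return float(np.trapezoid(tpr, fpr))
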