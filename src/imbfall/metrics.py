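"""Imbalance-aware evaluation under the fall-detection confusion convention.

IMPORTANT LABEL CONVENTION: the positive class is ADL (label 0, the
majority) and the negative class is fall (label 1, the minority):

* TP — ADL correctly classified as ADL
* TN — fall correctly detected as fall
* FP — a fall that was NOT detected (missed fall)
* FN — an ADL flagged as fall (false alarm)

Hence *sensitivity* = TP/(TP+FN) is ADL recall and *specificity* =
TN/(TN+FP) is fall recall — the number that matters most for a fall
detector, which is why the F-β score with β = 0.5 weights specificity more
heavily. Rates with a zero denominator are reported as missing (NaN) with a
warning, never as 0 or 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class MetricsError(ValueError):
    pass


ADL, FALL = 0, 1


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts plus percentage rates (positive class = ADL)."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    f_score: float
    beta: float
    auc: float  # percent, like the other rates

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])

    def to_text(self) -> str:
        return (
            f"n={self.n}  TP={self.tp} TN={self.tn} FP={self.fp} FN={self.fn}\n"
            f"accuracy    {self.accuracy:7.2f} %\n"
            f"sensitivity {self.sensitivity:7.2f} %   (ADL recall)\n"
            f"specificity {self.specificity:7.2f} %   (fall recall)\n"
            f"F-{self.beta:g}       {self.f_score:7.2f} %\n"
            f"AUC         {self.auc:7.2f} %\n"
        )


def confusion(true_labels, pred_labels) -> tuple[int, int, int, int]:
    """(tp, tn, fp, fn) with positive = ADL (0), negative = fall (1)."""
    t = np.asarray(true_labels).astype(int).ravel()
    p = np.asarray(pred_labels).astype(int).ravel()
    if t.shape != p.shape:
        raise MetricsError(f"length mismatch: {t.shape} vs {p.shape}")
    tp = int(np.sum((t == ADL) & (p == ADL)))
    tn = int(np.sum((t == FALL) & (p == FALL)))
    fp = int(np.sum((t == FALL) & (p == ADL)))  # missed fall
    fn = int(np.sum((t == ADL) & (p == FALL)))  # false alarm
    return tp, tn, fp, fn


def _rate(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN", stacklevel=3)
        return float("nan")
    return 100.0 * num / den


def rates(counts: tuple[int, int, int, int]) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent from (tp, tn, fp, fn)."""
    tp, tn, fp, fn = counts
    accuracy = _rate(tp + tn, tp + tn + fp + fn, "accuracy")
    sensitivity = _rate(tp, tp + fn, "sensitivity")
    specificity = _rate(tn, tn + fp, "specificity")
    return accuracy, sensitivity, specificity


def f_score(sensitivity: float, specificity: float, beta: float = 0.5) -> float:
    """F-β = (1+β²)·Sens·Spec / (β²·Sens + Spec), on percentages.

    β < 1 weights specificity (fall recall) more heavily; equal arguments
    return themselves for any β.
    """
    if beta < 0:
        raise MetricsError("beta must be >= 0")
    num = (1.0 + beta**2) * sensitivity * specificity
    den = beta**2 * sensitivity + specificity
    if den == 0:
        return 0.0
    return num / den


def roc_auc(minority_posteriors, true_labels) -> float:
    """Area under the ROC curve, in [0, 1].

    Computed as the normalized Mann–Whitney rank statistic on the minority
    (fall) posterior, ties counting one half: the probability that a random
    fall receives a higher fall score than a random ADL. Equivalently (by
    reflecting the score), the probability that a randomly chosen positive
    (ADL) outranks a randomly chosen negative under the ADL score, i.e. the
    trapezoidal area under the ROC built from all cut points.
    """
    scores = np.asarray(minority_posteriors, dtype=float).ravel()
    y = np.asarray(true_labels).astype(int).ravel()
    if scores.shape != y.shape:
        raise MetricsError("scores and labels must have equal length")
    n_pos = int(np.sum(y == FALL))
    n_neg = int(np.sum(y == ADL))
    if n_pos == 0 or n_neg == 0:
        raise MetricsError("roc_auc needs both classes present")
    # midrank of each score; rank-sum of the fall class
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty_like(scores)
    sorted_scores = scores[order]
    i = 0
    r = np.arange(1, scores.size + 1, dtype=float)
    while i < scores.size:
        j = i
        while j + 1 < scores.size and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = r[i : j + 1].mean()
        i = j + 1
    rank_sum = ranks[y == FALL].sum()
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve_points(minority_posteriors, true_labels) -> pd.DataFrame:
    """ROC points (false-positive rate vs true-positive rate of the fall
    score) at every distinct cut point, for plotting/export."""
    scores = np.asarray(minority_posteriors, dtype=float).ravel()
    y = np.asarray(true_labels).astype(int).ravel()
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    rows = []
    n_pos = np.sum(y == FALL)
    n_neg = np.sum(y == ADL)
    for thr in thresholds:
        pred = scores >= thr
        tpr = np.sum(pred & (y == FALL)) / n_pos if n_pos else np.nan
        fpr = np.sum(pred & (y == ADL)) / n_neg if n_neg else np.nan
        rows.append((thr, fpr, tpr))
    return pd.DataFrame(rows, columns=["threshold", "fpr", "tpr"])


def evaluate(
    true_labels,
    pred_labels,
    minority_posteriors=None,
    beta: float = 0.5,
) -> EvalReport:
    """Full report: confusion counts, percentage rates, F-β and AUC."""
    counts = confusion(true_labels, pred_labels)
    accuracy, sensitivity, specificity = rates(counts)
    f = f_score(sensitivity, specificity, beta)
    auc = (
        100.0 * roc_auc(minority_posteriors, true_labels)
        if minority_posteriors is not None
        else float("nan")
    )
    return EvalReport(*counts, accuracy, sensitivity, specificity, f, beta, auc)
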