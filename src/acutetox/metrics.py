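"""Regression and classification metric suite, including the generalized MCC.

Classification summaries follow the toxicology-model reporting conventions:
sensitivity and specificity are computed one-vs-rest per class and averaged
for multiclass endpoints, balanced accuracy (BA) is the arithmetic mean of
the averaged sensitivity and specificity, and the Matthews correlation
coefficient (MCC) uses its confusion-matrix generalization

    MCC = (c*s - sum_k p_k t_k) / sqrt((s^2 - sum_k p_k^2)(s^2 - sum_k t_k^2))

with c the correct count, s the total, and t_k / p_k the true/predicted
counts for class k; it reduces to the familiar binary MCC on 2x2 matrices.
R-squared is the coefficient of determination on the identity line, not a
squared correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "regression_metrics",
    "classification_metrics",
    "generalized_mcc",
    "balanced_accuracy",
    "cooper_stats",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix, rows = truth, columns = predicted."""

    counts: np.ndarray
    classes: tuple

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=int)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("confusion matrix must be square")
        if arr.shape[0] != len(self.classes):
            raise ValueError("class list must match matrix size")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", arr)


def confusion_matrix(truth, pred, classes=None) -> ConfusionMatrix:
    """Build a confusion matrix from label vectors (rows = truth)."""
    truth = list(truth)
    pred = list(pred)
    if len(truth) != len(pred):
        raise ValueError("truth and predictions must align")
    if classes is None:
        classes = sorted(set(truth) | set(pred))
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, pred):
        cm[index[t], index[p]] += 1
    return ConfusionMatrix(cm, tuple(classes))


def regression_metrics(pred, truth) -> dict:
    """R-squared (identity line), MAE and RMSE."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("need equal non-empty prediction and truth vectors")
    resid = pred - truth
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return {"r2": r2, "mae": mae, "rmse": rmse}


def generalized_mcc(cm: ConfusionMatrix) -> float:
    """Multiclass Matthews correlation of a confusion matrix."""
    C = cm.counts.astype(float)
    s = C.sum()
    c = np.trace(C)
    t = C.sum(axis=1)  # true counts per class
    p = C.sum(axis=0)  # predicted counts per class
    num = c * s - float(t @ p)
    den = math.sqrt(s**2 - float(p @ p)) * math.sqrt(s**2 - float(t @ t))
    if den == 0:
        return 0.0
    return num / den


def _per_class_sen_spe(cm: ConfusionMatrix) -> tuple[list[float], list[float]]:
    C = cm.counts.astype(float)
    total = C.sum()
    sens, spes = [], []
    for k in range(C.shape[0]):
        tp = C[k, k]
        fn = C[k].sum() - tp
        fp = C[:, k].sum() - tp
        tn = total - tp - fn - fp
        sens.append(tp / (tp + fn) if tp + fn > 0 else float("nan"))
        spes.append(tn / (tn + fp) if tn + fp > 0 else float("nan"))
    return sens, spes


def classification_metrics(cm: ConfusionMatrix, positive=None) -> dict:
    """SEN, SPE, BA and MCC from a confusion matrix.

    Binary matrices report the positive class's sensitivity/specificity
    (``positive`` defaults to the first class); multiclass matrices report
    one-vs-rest averages, skipping classes with an empty truth row.
    """
    sens, spes = _per_class_sen_spe(cm)
    if len(cm.classes) == 2:
        k = 0 if positive is None else list(cm.classes).index(positive)
        sen, spe = sens[k], spes[k]
    else:
        sen = float(np.nanmean(sens))
        spe = float(np.nanmean(spes))
    ba = (sen + spe) / 2.0
    return {"sen": sen, "spe": spe, "ba": ba, "mcc": generalized_mcc(cm)}


def balanced_accuracy(truth, pred) -> float:
    """BA from label vectors (convenience wrapper)."""
    return classification_metrics(confusion_matrix(truth, pred))["ba"]


def cooper_stats(cm: ConfusionMatrix, positive=None) -> dict:
    """Cooper statistics of a binary matrix: SEN, SPE, accuracy, FPR, FNR."""
    if len(cm.classes) != 2:
        raise ValueError("Cooper statistics require a binary confusion matrix")
    if cm.counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    sens, spes = _per_class_sen_spe(cm)
    k = 0 if positive is None else list(cm.classes).index(positive)
    sen, spe = sens[k], spes[k]
    acc = float(np.trace(cm.counts)) / float(cm.counts.sum())
    return {
        "sensitivity": sen,
        "specificity": spe,
        "accuracy": acc,
        "false_positive_rate": 1.0 - spe,
        "false_negative_rate": 1.0 - sen,
    }
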