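"""Confusion matrices and averaged recall / precision / F-measure / accuracy.

Conventions: confusion-matrix rows are the true activity, columns the
predicted one; per-class values are reported in percent; the averaged
recall and precision are unweighted (macro) means over classes, and the
summary F-measure is the harmonic mean of those two averages,

    F = 2 P R / (P + R).

(Some reports label such numbers "micro-averaged"; arithmetically they are
macro averages, which is what is implemented here — micro-averaged recall,
precision and F all collapse to plain accuracy for single-label problems.)
Display rounding is to one decimal, half away from zero; internal values
stay unrounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix


def confusion_matrix(y_true, y_pred, n_classes: int | None = None) -> np.ndarray:
    """Counts[i, j] = number of windows with true class i+1 predicted j+1."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label sequences differ in length")
    if min(y_true.min(), y_pred.min()) < 1:
        raise ValueError("labels are 1-based")
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max()))
    labels = np.arange(1, n_classes + 1)
    return _sk_confusion_matrix(y_true, y_pred, labels=labels)


def row_normalize(cm: np.ndarray) -> np.ndarray:
    """Row percentages: 100 * counts[i, j] / row_i total.

    Rows with no true instances yield NaN (an explicit undefined marker,
    never a silent zero).
    """
    cm = np.asarray(cm, dtype=np.float64)
    totals = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * cm / totals
    out[totals[:, 0] == 0] = np.nan
    return out


def display_round(x, decimals: int = 1):
    """Round half away from zero, matching printed-table conventions."""
    x = np.asarray(x, dtype=np.float64)
    factor = 10.0**decimals
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor


@dataclass
class MetricsReport:
    """Per-class and averaged classification measures, in percent."""

    recall: np.ndarray        # per class
    precision: np.ndarray     # per class
    f_measure: np.ndarray     # per class
    avg_recall: float
    avg_precision: float
    avg_f_measure: float      # harmonic mean of the two averages
    accuracy: float

    def to_frame(self) -> pd.DataFrame:
        n = len(self.recall)
        per_class = pd.DataFrame(
            {
                "class": np.arange(1, n + 1),
                "recall": self.recall,
                "precision": self.precision,
                "f_measure": self.f_measure,
            }
        )
        return per_class

    def summary(self) -> dict:
        return {
            "recall": self.avg_recall,
            "precision": self.avg_precision,
            "f_measure": self.avg_f_measure,
            "accuracy": self.accuracy,
        }


def averaged_measures(cm: np.ndarray) -> MetricsReport:
    """Averaged measures from a confusion matrix of counts (or of row
    percentages — recall is support-independent either way).
    """
    cm = np.asarray(cm, dtype=np.float64)
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    if (row == 0).any():
        raise ValueError("every class needs at least one true instance")
    diag = np.diag(cm)
    recall = 100.0 * diag / row
    precision = np.where(col > 0, 100.0 * diag / np.where(col > 0, col, 1), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_per = np.where(
            recall + precision > 0,
            2 * recall * precision / (recall + precision),
            0.0,
        )
    avg_r = float(recall.mean())
    avg_p = float(precision.mean())
    avg_f = 2 * avg_p * avg_r / (avg_p + avg_r) if avg_p + avg_r > 0 else 0.0
    accuracy = float(100.0 * diag.sum() / cm.sum())
    return MetricsReport(
        recall=recall,
        precision=precision,
        f_measure=f_per,
        avg_recall=avg_r,
        avg_precision=avg_p,
        avg_f_measure=float(avg_f),
        accuracy=accuracy,
    )
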