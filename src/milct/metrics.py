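"""Evaluation metrics for the binary reflex-detection task.

Per class c (one-vs-rest on the 2x2 confusion matrix): precision
TP/(TP+FP), sensitivity TP/(TP+FN), specificity TN/(TN+FP); accuracy is
global; F1 is the harmonic mean of precision and sensitivity (the
arithmetic mean is also reported); macro rows are unweighted means over
the two classes.  All reported as percentages.  Undefined ratios (zero
denominators) become NaN with a warning, never a silent zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

__all__ = ["MetricsReport", "confusion_matrix", "compute_metrics", "roc_auc",
           "dataset_summary"]


@dataclass
class MetricsReport:
    """Per-class and macro-averaged metrics (percent) for one evaluation."""

    cm: np.ndarray
    per_class: dict[int, dict[str, float]]
    macro: dict[str, float]
    accuracy: float
    fold: int | None = None
    roc: tuple[np.ndarray, np.ndarray] | None = None
    auc: float | None = None


def confusion_matrix(y_true, y_pred) -> np.ndarray:
    """2x2 counts, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    cm = np.zeros((2, 2), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def compute_metrics(cm: np.ndarray, fold: int | None = None) -> MetricsReport:
    cm = np.asarray(cm, dtype=np.int64)
    if cm.shape != (2, 2) or (cm < 0).any():
        raise ValueError("confusion matrix must be 2x2 nonnegative counts")
    total = int(cm.sum())
    if total == 0:
        raise ValueError("confusion matrix is empty")
    acc = 100.0 * (cm[0, 0] + cm[1, 1]) / total
    per_class: dict[int, dict[str, float]] = {}
    for c in (0, 1):
        o = 1 - c
        tp, fn = cm[c, c], cm[c, o]
        fp, tn = cm[o, c], cm[o, o]
        pre = _ratio(tp, tp + fp, f"precision(class {c})")
        sen = _ratio(tp, tp + fn, f"sensitivity(class {c})")
        spe = _ratio(tn, tn + fp, f"specificity(class {c})")
        with np.errstate(invalid="ignore"):
            f1 = 2 * pre * sen / (pre + sen) if (pre + sen) else float("nan")
            f1_arith = (pre + sen) / 2.0
        per_class[c] = {
            "ACC": acc, "PRE": 100 * pre, "SEN": 100 * sen, "SPE": 100 * spe,
            "F1": 100 * f1, "F1_arith": 100 * f1_arith,
        }
    macro = {k: float(np.mean([per_class[0][k], per_class[1][k]]))
             for k in per_class[0]}
    return MetricsReport(cm=cm, per_class=per_class, macro=macro,
                         accuracy=acc, fold=fold)


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points (threshold sweep over unique scores) and trapezoid AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def dataset_summary(manifest: pd.DataFrame) -> dict:
    """Per-class (and per-split) counts with percentage proportions.

    Proportions are count/total as percent, rounded to 2 decimals.
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    total = len(manifest)
    out: dict = {"total": total, "per_class": {}, "per_split": {}}
    for label, n in manifest["label"].value_counts().sort_index().items():
        out["per_class"][int(label)] = {
            "count": int(n),
            "pct": round(100.0 * n / total, 2),
        }
    if "split" in manifest.columns:
        for split, sub in manifest.groupby("split"):
            out["per_split"][str(split)] = {
                "count": int(len(sub)),
                "per_class": {int(k): int(v) for k, v in
                              sub["label"].value_counts().sort_index().items()},
            }
    return out
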