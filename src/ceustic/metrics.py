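"""Multiclass evaluation metrics.

All metrics are computed from an N x N confusion matrix with rows indexed
by the true class and columns by the predicted class:

* categorical accuracy — trace / total;
* micro-averaged F1 — precision and recall pooled over per-class TP/FP/FN
  (for single-label problems this is algebraically identical to accuracy);
* macro-averaged F1 — the harmonic mean of the unweighted per-class mean
  precision and mean recall;
* multiclass Matthews correlation coefficient (the Gorodkin R_K statistic)

      MCC = (c*S - sum_i p_i t_i) /
            sqrt((S^2 - sum_i p_i^2) * (S^2 - sum_i t_i^2))

  where c is the number of correct predictions, S the number of samples,
  t_i the true count and p_i the predicted count of class i.

0/0 situations (per-class ratios in the macro average, a zero MCC
denominator from a constant predictor) are defined as 0 with a warning.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "confusion_matrix",
    "categorical_accuracy",
    "f1_scores",
    "mcc_multiclass",
    "metrics_report",
    "REPORT_COLUMNS",
]

#: Canonical metric names used in report tables.
REPORT_COLUMNS = ("Categorical Accuracy", "F1 Micro", "F1 Macro", "MCC")


def confusion_matrix(
    y_true: Sequence[int], y_pred: Sequence[int], n_classes: int = 5
) -> np.ndarray:
    """Confusion matrix with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label and prediction vectors must have equal length")
    if np.any((y_true < 0) | (y_true >= n_classes) | (y_pred < 0) | (y_pred >= n_classes)):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _validate(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("confusion matrix counts must be non-negative")
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    return cm


def categorical_accuracy(cm: np.ndarray) -> float:
    """Correct predictions divided by total predictions."""
    cm = _validate(cm)
    return float(np.trace(cm) / cm.sum())


def _safe_ratio(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    zero = den == 0
    if np.any(zero):
        warnings.warn(f"{what}: 0/0 for class(es) {np.flatnonzero(zero).tolist()}, "
                      "defined as 0", stacklevel=3)
    out[~zero] = num[~zero] / den[~zero]
    return out


def f1_scores(cm: np.ndarray) -> tuple[float, float]:
    """(F1 micro, F1 macro) from per-class TP/FP/FN."""
    cm = _validate(cm)
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp

    prc_micro = tp.sum() / (tp.sum() + fp.sum())
    rec_micro = tp.sum() / (tp.sum() + fn.sum())
    f1_micro = (
        0.0 if prc_micro + rec_micro == 0
        else 2 * prc_micro * rec_micro / (prc_micro + rec_micro)
    )

    prc_macro = float(_safe_ratio(tp, tp + fp, "macro precision").mean())
    rec_macro = float(_safe_ratio(tp, tp + fn, "macro recall").mean())
    if prc_macro + rec_macro == 0:
        f1_macro = 0.0
    else:
        f1_macro = 2 * prc_macro * rec_macro / (prc_macro + rec_macro)
    return float(f1_micro), float(f1_macro)


def mcc_multiclass(cm: np.ndarray) -> float:
    """Multiclass Matthews correlation coefficient (Gorodkin R_K)."""
    cm = _validate(cm).astype(float)
    S = cm.sum()
    c = np.trace(cm)
    t = cm.sum(axis=1)  # true counts per class
    p = cm.sum(axis=0)  # predicted counts per class
    num = c * S - (p * t).sum()
    den_sq = (S**2 - (p**2).sum()) * (S**2 - (t**2).sum())
    if den_sq <= 0:
        warnings.warn("MCC denominator is zero (constant truth or predictor); "
                      "defined as 0", stacklevel=2)
        return 0.0
    return float(num / np.sqrt(den_sq))


def metrics_report(cm: np.ndarray) -> dict[str, float]:
    """All four metrics keyed by their canonical report names."""
    f1_micro, f1_macro = f1_scores(cm)
    return {
        "Categorical Accuracy": categorical_accuracy(cm),
        "F1 Micro": f1_micro,
        "F1 Macro": f1_macro,
        "MCC": mcc_multiclass(cm),
    }


def report_frame(rows: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Stack metric dicts (e.g. {'Training': ..., 'Validation': ...}) into a table."""
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(REPORT_COLUMNS))
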