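"""Evaluation metrics for the classification and regression tasks.

Classification follows the usual convention with the interference mode as
the positive class: precision = TP/(TP+FP), recall = TP/(TP+FN), F1 the
harmonic mean of the two, accuracy the share of correct predictions (chance
on balanced binary labels is 0.5). Ratios with a zero denominator are
reported as ``None`` ("not available"), never silently as 0, and are
excluded from aggregates.

Regression reports the root mean square error and the Pearson correlation of
predictions against targets; the correlation is ``None`` when either side is
constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError


@dataclass(frozen=True)
class EvalReport:
    """Metrics of one evaluation (one fold, or an aggregate)."""

    n: int = 0
    # classification
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    tp: int | None = None
    fp: int | None = None
    fn: int | None = None
    tn: int | None = None
    # regression
    rmse: float | None = None
    pearson_r: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) with label 1 as the positive class."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have identical shape")
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    return tp, fp, fn, tn


def classification_report(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    """Accuracy, precision, recall and F1 from hard binary predictions."""
    if len(np.asarray(y_true)) == 0:
        raise EmptyInputError("cannot evaluate on zero test windows")
    tp, fp, fn, tn = confusion_counts(y_true, y_pred)
    total = tp + fp + fn + tn
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision is not None and recall is not None:
        f1 = 0.0
    else:
        f1 = None
    return EvalReport(
        n=total, accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        tp=tp, fp=fp, fn=fn, tn=tn,
    )


def regression_report(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    """RMSE and Pearson r of predictions vs. targets."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.size == 0:
        raise EmptyInputError("cannot evaluate on zero test targets")
    if y_true.shape != y_pred.shape:
        raise ValueError("target/prediction arrays must have identical shape")
    rmse = float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
    r = None
    if y_true.size >= 2 and np.std(y_true) > 0 and np.std(y_pred) > 0:
        r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return EvalReport(n=int(y_true.size), rmse=rmse, pearson_r=r)


def majority_vote(window_pred: np.ndarray) -> int:
    """Walk-level label from window-level hard predictions (ties -> positive)."""
    window_pred = np.asarray(window_pred).astype(int)
    if window_pred.size == 0:
        raise EmptyInputError("majority vote over zero windows")
    return int(window_pred.mean() >= 0.5)


def aggregate_reports(reports: list[EvalReport]) -> dict:
    """Mean and SD over folds for every defined metric; counts undefined ones.

    Undefined (None) metric values are excluded from the mean/SD; their count
    is reported so silently skewed aggregates cannot go unnoticed.
    """
    out: dict = {"n_folds": len(reports)}
    for name in ("accuracy", "precision", "recall", "f1", "rmse", "pearson_r"):
        vals = [getattr(r, name) for r in reports]
        defined = [v for v in vals if v is not None]
        out[f"{name}_undefined"] = len(vals) - len(defined)
        if defined:
            out[f"{name}_mean"] = float(np.mean(defined))
            out[f"{name}_sd"] = float(np.std(defined))
        else:
            out[f"{name}_mean"] = None
            out[f"{name}_sd"] = None
    return out
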