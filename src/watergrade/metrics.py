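"""Classifier evaluation: accuracy, precision, recall and ordinal RMSE.

Per-class true/false positive/negative counts come from the k x k confusion
matrix.  Accuracy is the micro form (total correct / total).  Precision and
recall are computed per class and macro-averaged (classes absent from both
the actual and predicted labels are excluded).  RMSE is computed on the
ordinal class encoding 1..6 (I .. poor V), so a one-class misgrade
contributes an error of 1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass
class Evaluation:
    accuracy: float
    precision_macro: float
    recall_macro: float
    precision_micro: float
    recall_micro: float
    rmse: float
    per_class: pd.DataFrame
    confusion: pd.DataFrame

    def to_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "precision_micro": self.precision_micro,
            "recall_micro": self.recall_micro,
            "rmse": self.rmse,
        }


def _check_labels(name: str, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim != 1 or y.size < 1:
        raise ValidationError(f"{name} must be a non-empty 1-D label array")
    yi = y.astype(int)
    if not np.array_equal(yi, y.astype(float)):
        raise ValidationError(f"{name} labels must be integers")
    if yi.min() < 1 or yi.max() > 6:
        raise ValidationError(f"{name} labels must lie in 1..6")
    return yi


def confusion_matrix(actual: np.ndarray, predicted: np.ndarray, classes: list[int]) -> pd.DataFrame:
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((k, k), dtype=int)
    for a, p in zip(actual, predicted):
        mat[idx[a], idx[p]] += 1
    return pd.DataFrame(mat, index=classes, columns=classes)


def evaluate(actual, predicted) -> Evaluation:
    """Evaluate predictions against actual ordinal class labels (1..6)."""
    ya = _check_labels("actual", np.asarray(actual))
    yp = _check_labels("predicted", np.asarray(predicted))
    if ya.size != yp.size:
        raise ValidationError(f"length mismatch: {ya.size} actual vs {yp.size} predicted")

    classes = sorted(set(ya.tolist()) | set(yp.tolist()))
    cm = confusion_matrix(ya, yp, classes)
    mat = cm.to_numpy()
    total = int(mat.sum())

    rows = []
    for i, c in enumerate(classes):
        tp = int(mat[i, i])
        fp = int(mat[:, i].sum() - tp)
        fn = int(mat[i, :].sum() - tp)
        tn = total - tp - fp - fn
        if tp + fp == 0:
            log.info("class %d was never predicted; precision defined as 0", c)
            prec = 0.0
        else:
            prec = tp / (tp + fp)
        rec = tp / (tp + fn) if tp + fn else 0.0
        rows.append(
            {"class": c, "tp": tp, "fp": fp, "fn": fn, "tn": tn,
             "precision": prec, "recall": rec}
        )
    per_class = pd.DataFrame(rows)

    accuracy = float(np.trace(mat) / total)
    rmse = float(np.sqrt(np.mean((yp.astype(float) - ya.astype(float)) ** 2)))
    return Evaluation(
        accuracy=accuracy,
        precision_macro=float(per_class["precision"].mean()),
        recall_macro=float(per_class["recall"].mean()),
        precision_micro=accuracy,
        recall_micro=accuracy,
        rmse=rmse,
        per_class=per_class,
        confusion=cm,
    )
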