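"""Evaluation metrics: accuracy, macro precision/recall/F1, binary ROC-AUC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_recall_fscore_support,
    roc_auc_score,
)


@dataclass
class MetricsReport:
    """Per-dataset evaluation summary.

    ``roc_auc`` and ``f1`` are populated for binary problems only (positive
    class = the larger class label); ``None`` marks an undefined metric, e.g.
    ROC-AUC on single-class data.
    """

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray
    roc_auc: float | None = None
    f1: float | None = None

    def as_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "confusion": self.confusion.tolist(),
        }
        if self.roc_auc is not None:
            out["roc_auc"] = self.roc_auc
        if self.f1 is not None:
            out["f1"] = self.f1
        return out


def evaluate(model, X, y) -> MetricsReport:
    """Score a fitted classifier on (X, y).

    Macro metrics are unweighted per-class means; a class never predicted
    contributes precision 0 rather than NaN.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("cannot evaluate on empty data")
    y_pred = model.predict(X)
    labels = list(model.classes_)
    acc = accuracy_score(y, y_pred)
    prec, rec, f1m, _ = precision_recall_fscore_support(
        y, y_pred, labels=labels, average="macro", zero_division=0
    )
    cm = confusion_matrix(y, y_pred, labels=labels)
    auc = binf1 = None
    if len(labels) == 2:
        pos = labels[1]
        if np.unique(y).size < 2:
            auc = None  # undefined on single-class data
        else:
            scores = model.predict_proba(X)[:, 1]
            auc = float(roc_auc_score(y == pos, scores))
        binf1 = float(f1_score(y, y_pred, pos_label=pos, zero_division=0))
    return MetricsReport(
        accuracy=float(acc),
        macro_precision=float(prec),
        macro_recall=float(rec),
        macro_f1=float(f1m),
        confusion=cm,
        roc_auc=auc,
        f1=binf1,
    )
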