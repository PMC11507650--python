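"""Multiclass evaluation: confusion matrix and one-vs-rest P/R/F1.

Per-class precision, recall and F1 treat that class as positive and all
other origins as negative; the headline accuracy is the multiclass
trace / total.  Zero-denominator metrics are reported as 0 with an
explicit flag so reports stay serializable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ClassificationReport",
    "confusion_matrix",
    "per_class_metrics",
    "overall_accuracy",
    "evaluate",
    "f1_score",
]


def confusion_matrix(
    true_labels: Sequence, pred_labels: Sequence, class_order: Sequence
) -> np.ndarray:
    """K x K count matrix: entry (i, j) = # samples of true class i predicted j."""
    true_labels = list(true_labels)
    pred_labels = list(pred_labels)
    if len(true_labels) != len(pred_labels):
        raise ValueError("true and predicted label sequences differ in length")
    lut = {c: i for i, c in enumerate(class_order)}
    K = len(lut)
    if K != len(list(class_order)):
        raise ValueError("class_order contains duplicates")
    cm = np.zeros((K, K), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        if t not in lut:
            raise ValueError(f"unknown true label {t!r}")
        if p not in lut:
            raise ValueError(f"unknown predicted label {p!r}")
        cm[lut[t], lut[p]] += 1
    return cm


def per_class_metrics(confusion: np.ndarray, class_index: int) -> dict:
    """One-vs-rest precision, recall and F1 for one class (as fractions).

    ``P = TP/(TP+FP)``, ``R = TP/(TP+FN)``, ``F1 = 2PR/(P+R)``.  A zero
    denominator yields a 0 metric and sets the ``undefined`` flag.
    """
    cm = np.asarray(confusion)
    _check_confusion(cm)
    i = class_index
    tp = float(cm[i, i])
    fp = float(cm[:, i].sum() - cm[i, i])
    fn = float(cm[i, :].sum() - cm[i, i])
    undefined = []
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, undefined = 0.0, undefined + ["P"]
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, undefined = 0.0, undefined + ["R"]
    f1 = f1_score(precision, recall)
    if precision + recall == 0:
        undefined = undefined + ["F1"]
    return {"P": precision, "R": recall, "F1": f1, "undefined": undefined}


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def overall_accuracy(confusion: np.ndarray) -> float:
    """Multiclass accuracy: trace / total."""
    cm = np.asarray(confusion)
    _check_confusion(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    return float(np.trace(cm) / total)


def _check_confusion(cm: np.ndarray) -> None:
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be >= 0")


@dataclass
class ClassificationReport:
    """Confusion matrix with per-class one-vs-rest metrics and accuracy."""

    confusion: np.ndarray
    class_order: list
    per_class: list[dict] = field(init=False)
    acc: float = field(init=False)

    def __post_init__(self) -> None:
        cm = np.asarray(self.confusion, dtype=int)
        _check_confusion(cm)
        if cm.shape[0] != len(self.class_order):
            raise ValueError("confusion size does not match class_order")
        self.confusion = cm
        self.per_class = [per_class_metrics(cm, i) for i in range(cm.shape[0])]
        self.acc = overall_accuracy(cm)

    @property
    def n_total(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        """JSON-ready report; percentages rounded only here, at presentation."""
        return {
            "acc": round(100.0 * self.acc, 2),
            "classes": [
                {
                    "label": str(label),
                    "P": round(100.0 * m["P"], 2),
                    "R": round(100.0 * m["R"], 2),
                    "F1": round(100.0 * m["F1"], 2),
                    "n": int(self.confusion[i, :].sum()),
                    "undefined": m["undefined"],
                }
                for i, (label, m) in enumerate(zip(self.class_order, self.per_class))
            ],
            "confusion": self.confusion.tolist(),
        }


def evaluate(true_labels: Sequence, pred_labels: Sequence, class_order: Sequence) -> ClassificationReport:
    return ClassificationReport(
        confusion=confusion_matrix(true_labels, pred_labels, class_order),
        class_order=list(class_order),
    )
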