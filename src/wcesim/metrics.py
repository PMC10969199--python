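"""Confusion-matrix evaluation metrics.

Accuracy is trace/total.  Precision, recall and F1 are defined per class
one-vs-rest (precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2PR/(P+R)) and macro-averaged without weighting; any 0/0 rate is
reported as 0, which affects classes that are never predicted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValidationError(
                f"counts shape {self.counts.shape} != ({k}, {k}) for {k} classes"
            )
        if (self.counts < 0).any():
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(
    y_true: Sequence[str], y_pred: Sequence[str], class_names: Sequence[str]
) -> ConfusionMatrix:
    """Tally a confusion matrix from parallel label sequences."""
    if len(y_true) != len(y_pred):
        raise ValidationError(f"label lengths differ: {len(y_true)} vs {len(y_pred)}")
    index = {c: i for i, c in enumerate(class_names)}
    k = len(index)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index:
            raise ValidationError(f"unknown true label {t!r}")
        if p not in index:
            raise ValidationError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_names=list(class_names))


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def scores(cm: ConfusionMatrix) -> dict:
    """Accuracy plus per-class and macro precision/recall/F1."""
    if cm.total == 0:
        raise ValidationError("confusion matrix is empty")
    counts = cm.counts.astype(np.float64)
    accuracy = float(np.trace(counts)) / cm.total
    per_class: dict[str, dict[str, float]] = {}
    ps, rs, fs = [], [], []
    for i, name in enumerate(cm.class_names):
        tp = counts[i, i]
        fp = counts[:, i].sum() - tp
        fn = counts[i, :].sum() - tp
        p = _safe_div(tp, tp + fp)
        r = _safe_div(tp, tp + fn)
        f1 = _safe_div(2 * p * r, p + r)
        per_class[name] = {"precision": p, "recall": r, "f1": f1}
        ps.append(p)
        rs.append(r)
        fs.append(f1)
    return {
        "accuracy": accuracy,
        "per_class": per_class,
        "macro_precision": float(np.mean(ps)),
        "macro_recall": float(np.mean(rs)),
        "macro_f1": float(np.mean(fs)),
    }
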