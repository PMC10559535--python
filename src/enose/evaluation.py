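"""Confusion-matrix evaluation with a fixed orientation.

Rows are true labels (0 = benign hyperplasia on top, 1 = prostate cancer
below), columns are predicted labels (0 left, 1 right), so counts[1][0] is
a false negative (a cancer instance called benign) and counts[0][1] a false
positive.  The orientation is printed on every report so the off-diagonal
cells are never ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

ORIENTATION = "rows: true label 0,1 (top-down); columns: predicted label 0,1 (left-right)"


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: tuple[tuple[int, int], tuple[int, int]]

    @property
    def total(self) -> int:
        return sum(sum(row) for row in self.counts)

    def as_array(self) -> np.ndarray:
        return np.array(self.counts, dtype=int)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: tuple[float, float]
    recall: tuple[float, float]
    f1: tuple[float, float]
    support: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "orientation": ORIENTATION,
            "accuracy": self.accuracy,
            "precision": list(self.precision),
            "recall": list(self.recall),
            "f1": list(self.f1),
            "support": list(self.support),
        }


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """2x2 confusion counts, counts[i][j] = #{true = i, predicted = j}."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise EvaluationError("y_true and y_pred must be equal-length 1-D sequences")
    if yt.size and (not set(np.unique(yt)) <= {0, 1} or not set(np.unique(yp)) <= {0, 1}):
        raise EvaluationError("labels must lie in {0, 1}")
    counts = tuple(
        tuple(int(np.sum((yt == i) & (yp == j))) for j in (0, 1)) for i in (0, 1)
    )
    return ConfusionMatrix(counts)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy plus per-class precision, recall, F1 and support.

    recall_c = counts[c][c] / row_c; precision_c = counts[c][c] / col_c;
    a zero denominator yields 0 with a warning rather than an error.
    """
    arr = cm.as_array()
    total = int(arr.sum())
    if total == 0:
        raise EvaluationError("empty confusion matrix")

    def _safe(num: int, den: int, what: str) -> float:
        if den == 0:
            warnings.warn(f"{what}: zero denominator, reporting 0")
            return 0.0
        return float(num) / float(den)

    precision = tuple(_safe(arr[c, c], int(arr[:, c].sum()), f"precision[{c}]") for c in (0, 1))
    recall = tuple(_safe(arr[c, c], int(arr[c, :].sum()), f"recall[{c}]") for c in (0, 1))
    f1 = tuple(
        (2 * p * r / (p + r)) if (p + r) > 0 else 0.0 for p, r in zip(precision, recall)
    )
    return MetricsReport(
        accuracy=float(np.trace(arr)) / total,
        precision=precision,
        recall=recall,
        f1=f1,
        support=(int(arr[0].sum()), int(arr[1].sum())),
    )


def patient_vote(
    y_pred: Sequence[int], patient_ids: Sequence[str]
) -> dict[str, int]:
    """Optional patient-level aggregation: majority vote over a patient's
    instance predictions; exact ties go to class 1 (favoring sensitivity)."""
    yp = np.asarray(y_pred, dtype=int)
    if len(yp) != len(patient_ids):
        raise EvaluationError("predictions and patient ids must align")
    votes: dict[str, list[int]] = {}
    for pred, pid in zip(yp, patient_ids):
        votes.setdefault(pid, []).append(int(pred))
    return {
        pid: (1 if sum(v) * 2 >= len(v) else 0) for pid, v in votes.items()
    }
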