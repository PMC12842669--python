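"""Confusion-count classification metrics for the binary abnormal-vs-normal task.

Positive class = 1 (abnormal).  Any metric whose denominator is zero is
returned as ``None`` (the undefined marker) rather than silently as 0, so
seed-averaged tables can distinguish "no positives predicted" from
"perfectly wrong".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from radnorm.errors import ContractError

__all__ = ["ConfusionCounts", "MetricsBundle", "confusion", "metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ContractError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsBundle:
    """Derived metrics; ``None`` marks an undefined (zero-denominator) value."""

    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Tally TP/FP/TN/FN for binary vectors (positive class = 1)."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape or t.ndim != 1 or t.size < 1:
        raise ContractError(
            f"y_true and y_pred must be equal-length 1-D vectors, got {t.shape} vs {p.shape}"
        )
    for name, v in (("y_true", t), ("y_pred", p)):
        if not np.isin(v, (0, 1)).all():
            raise ContractError(f"{name} must contain only 0/1 entries")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(counts: ConfusionCounts) -> MetricsBundle:
    """Accuracy, precision, recall/sensitivity, F1 and specificity from counts.

    ``accuracy = (TP+TN)/total``; ``precision = TP/(TP+FP)``;
    ``recall = sensitivity = TP/(TP+FN)``; ``specificity = TN/(TN+FP)``;
    ``f1`` is the harmonic mean of precision and recall (undefined when
    either is undefined or both are zero).
    """
    if counts.total < 1:
        raise ContractError("metrics need at least one sample")
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    recall = _ratio(counts.tp, counts.tp + counts.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricsBundle(
        accuracy=(counts.tp + counts.tn) / counts.total,
        precision=precision,
        recall=recall,
        f1=f1,
        sensitivity=recall,
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
    )
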