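"""Confusion-matrix statistics and rank-based AUC.

Positive class is "deleterious" (D) throughout: sensitivity is recall on
deleterious variants.  Percentages are reported to two decimals; internal
values keep full precision.  Statistics with a zero denominator are
returned as None ("undefined"), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

POSITIVE = "D"
NEGATIVE = "ND"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n < 1:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(truth: Sequence[str], pred: Sequence[str]) -> ConfusionMatrix:
    """2×2 counts with positive = deleterious ('D')."""
    if len(truth) != len(pred):
        raise ValueError("truth and pred must have equal length")
    t = np.asarray([x == POSITIVE for x in truth])
    p = np.asarray([x == POSITIVE for x in pred])
    return ConfusionMatrix(
        tp=int((t & p).sum()),
        tn=int((~t & ~p).sum()),
        fp=int((~t & p).sum()),
        fn=int((t & ~p).sum()),
    )


def summarize(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Accuracy, sensitivity and specificity as rounded percentages.

    Values are percentages rounded to 2 decimals (matching clinical
    reporting convention); a statistic whose denominator is zero is None.
    """

    def pct(num: int, den: int) -> float | None:
        return round(100.0 * num / den, 2) if den > 0 else None

    return {
        "accuracy": pct(cm.tp + cm.tn, cm.n),
        "sensitivity": pct(cm.tp, cm.tp + cm.fn),
        "specificity": pct(cm.tn, cm.tn + cm.fp),
    }


def auc(scores: Sequence[float], truth: Sequence[str | int]) -> float | None:
    """Area under the ROC curve via the Mann–Whitney rank statistic.

    Equals the probability that a uniformly drawn positive outscores a
    uniformly drawn negative, ties counting one half; mid-ranks handle
    tied scores.  Returns None when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray([x == POSITIVE or x == 1 for x in truth])
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class ValidationReport:
    """Confusion matrix + summary statistics for one validation harness."""

    cm: ConfusionMatrix | None
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    auc: float | None = None
    details: dict = None

    @classmethod
    def from_confusion(
        cls, cm: ConfusionMatrix, auc_value: float | None = None, **details
    ) -> "ValidationReport":
        s = summarize(cm)
        return cls(
            cm=cm,
            accuracy=s["accuracy"],
            sensitivity=s["sensitivity"],
            specificity=s["specificity"],
            auc=auc_value,
            details=details or {},
        )

    def to_json_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }
        if self.cm is not None:
            out["confusion"] = {
                "tp": self.cm.tp, "tn": self.cm.tn,
                "fp": self.cm.fp, "fn": self.cm.fn,
            }
        out.update(self.details or {})
        return out
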