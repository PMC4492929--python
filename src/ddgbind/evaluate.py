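"""Benchmark flags and ROC-style metrics for ddG predictions.

Predicted/experimental pairs are assigned one of four outcomes using two
magnitude thresholds: a prediction "calls" an effect when |ddG_calc| >= 1.5
kcal/mol and calls no effect when |ddG_calc| < 0.5 kcal/mol (same bands for
the experimental value):

    tp   |calc| >= 1.5, |exp| >= 1.5, same sign
    fp   |calc| >= 1.5, |exp| < 0.5
    tn   |calc| < 0.5,  |exp| < 0.5
    fn   |calc| < 0.5,  |exp| >= 1.5

Pairs falling in no cell — either value in the middle band [0.5, 1.5), or
two large values of opposite sign — are explicitly "unclassified" and are
excluded from the counts (this is why benchmark totals are well below the
dataset size).  The sign of 0 counts as positive.

Six summary metrics follow: accuracy, sensitivity, specificity, precision,
negative predictive value and the Matthews correlation coefficient.  MCC
uses the conventional numerator tp*tn - fp*fn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

#: |ddG| at or above this is a called (positive) effect, kcal/mol
CALL_THRESHOLD = 1.5
#: |ddG| below this is a called no-effect (negative), kcal/mol
NO_CALL_THRESHOLD = 0.5

FLAGS = ("tp", "tn", "fp", "fn", "unclassified")


def _sign(x: float) -> int:
    # zero counts as positive
    return -1 if x < 0 else 1


def assign_flag(ddg_calc: float, ddg_exp: float) -> str:
    """Outcome flag of one prediction: tp, tn, fp, fn or unclassified."""
    if not (math.isfinite(ddg_calc) and math.isfinite(ddg_exp)):
        raise ValueError("ddG values must be finite")
    ac, ae = abs(ddg_calc), abs(ddg_exp)
    if ac >= CALL_THRESHOLD:
        if ae >= CALL_THRESHOLD:
            return "tp" if _sign(ddg_calc) == _sign(ddg_exp) else "unclassified"
        if ae < NO_CALL_THRESHOLD:
            return "fp"
        return "unclassified"
    if ac < NO_CALL_THRESHOLD:
        if ae < NO_CALL_THRESHOLD:
            return "tn"
        if ae >= CALL_THRESHOLD:
            return "fn"
        return "unclassified"
    return "unclassified"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    n_unclassified: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn, self.n_unclassified) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total_classified(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_pairs(cls, calc: Iterable[float], exp: Iterable[float]
                   ) -> "ConfusionCounts":
        counts = {flag: 0 for flag in FLAGS}
        for c, e in zip(calc, exp, strict=True):
            counts[assign_flag(c, e)] += 1
        return cls(tp=counts["tp"], tn=counts["tn"], fp=counts["fp"],
                   fn=counts["fn"], n_unclassified=counts["unclassified"])


@dataclass(frozen=True)
class RocMetrics:
    """Six summary metrics; ``None`` where the denominator is zero."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    npv: float | None
    mcc: float | None

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "precision": self.precision,
                "npv": self.npv, "mcc": self.mcc}


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def roc_metrics(counts: ConfusionCounts) -> RocMetrics:
    """Summary metrics of a confusion-count table.

    MCC is computed with the conventional numerator tp*tn - fp*fn.  Any
    metric whose denominator is zero is reported as None.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return RocMetrics(
        accuracy=_ratio(tn + tp, tn + tp + fn + fp),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        precision=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        mcc=(tp * tn - fp * fn) / mcc_den if mcc_den > 0 else None,
    )
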