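"""Confusion-matrix scoring with the EZ-positive convention.

Class 0 (epileptogenic) is the positive class: TP counts EZ events
classified as EZ, TN counts non-EZ events classified as non-EZ.
Scores are percentages:

    sensitivity = 100 * TP / (TP + FN)
    specificity = 100 * TN / (TN + FP)
    accuracy    = 100 * (TP + TN) / (TP + FN + TN + FP)

A zero denominator yields NaN (an undefined-score marker), never an
exception.  Round aggregation reports mean ± sample SD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "ScoreTriple",
    "RoundsSummary",
    "confusion",
    "scores",
    "summarize_rounds",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class ScoreTriple:
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass(frozen=True)
class RoundsSummary:
    """Mean ± SD of each score over evaluation rounds."""

    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    accuracy_mean: float
    accuracy_sd: float
    n_rounds: int


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count the four outcomes with class 0 (EZ) as positive."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for name, v in (("true", y_true), ("predicted", y_pred)):
        if v.size and not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} labels must be 0 or 1")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 0) & (y_pred == 1))),
        fp=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 1) & (y_pred == 1))),
    )


def _ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else math.nan


def scores(counts: ConfusionCounts) -> ScoreTriple:
    """Sensitivity, specificity and accuracy in percent."""
    return ScoreTriple(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
    )


def summarize_rounds(rounds) -> RoundsSummary:
    """Mean and sample SD (n-1 denominator) of each score over rounds.

    ``rounds`` is a sequence of :class:`ScoreTriple` or an object with a
    ``score_triples()`` method.  A single round reports SD = 0.
    """
    if hasattr(rounds, "score_triples"):
        rounds = rounds.score_triples()
    triples = list(rounds)
    if not triples:
        raise ValueError("need at least one round")
    arrays = {
        name: np.array([getattr(t, name) for t in triples])
        for name in ("sensitivity", "specificity", "accuracy")
    }
    if len(triples) == 1:
        logger.info("single round: SD reported as 0")
    out = {}
    for name, vals in arrays.items():
        out[f"{name}_mean"] = float(np.nanmean(vals))
        out[f"{name}_sd"] = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0
    return RoundsSummary(n_rounds=len(triples), **out)
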