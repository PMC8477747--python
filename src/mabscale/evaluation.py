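"""Prediction-accuracy statistics: fold errors, AFE, dose-range checks.

The accuracy of a clearance prediction is judged by the ratio
predicted/observed. Ratios are binned into the field's customary
categories — within 2-fold ([0.5, 2], the usual acceptability band),
within 1.5-fold ([0.5, 1.5]), over-prediction (> 2) and under-prediction
(< 0.5) — and summarised by the average fold error,

    AFE = 10^(mean(log10(predicted/observed))),

the geometric mean ratio; AFE = 1 means no systematic bias, 0.7 means
30% mean under-prediction. Bin boundaries are closed on the inner
intervals so the three-way partition {within 2-fold, over, under} is
exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .species import round_half_away

__all__ = [
    "FoldClass",
    "EvaluationSummary",
    "DoseRangeCheck",
    "fold_ratio",
    "classify_fold",
    "afe",
    "summarize",
    "check_dose_range",
]


@dataclass(frozen=True)
class FoldClass:
    """Category flags for one predicted/observed ratio."""

    within_2fold: bool
    within_1p5fold: bool
    over_2fold: bool
    under_0p5fold: bool


@dataclass(frozen=True)
class EvaluationSummary:
    """Fold-error bin counts and AFE for one species x method block."""

    species: str
    method: str
    n: int
    n_within_2fold: int
    n_within_1p5fold: int
    n_over: int
    n_under: int
    afe: float

    def __post_init__(self) -> None:
        if self.n_within_2fold + self.n_over + self.n_under != self.n:
            raise ValueError("fold-error bins must partition the n ratios")
        if self.n_within_1p5fold > self.n_within_2fold:
            raise ValueError("1.5-fold bin cannot exceed the 2-fold bin")
        if self.afe <= 0:
            raise ValueError(f"afe must be > 0, got {self.afe}")

    def percent(self, count: int) -> int:
        """A bin count as an integer percentage of n (report convention)."""
        return int(round_half_away(100.0 * count / self.n))


@dataclass(frozen=True)
class DoseRangeCheck:
    """Whether a projected dose falls inside the observed clinical range."""

    mab_id: str
    predicted_mgkg: float
    range_low: float
    range_high: float
    within: bool


def fold_ratio(predicted: float, observed: float) -> float:
    """Predicted/observed clearance ratio."""
    if predicted <= 0 or observed <= 0:
        raise ValueError(
            f"predicted and observed must be > 0, got {predicted}, {observed}"
        )
    return predicted / observed


def classify_fold(ratio: float) -> FoldClass:
    """Bin one ratio; exactly one of {within 2-fold, over, under} is set."""
    if ratio <= 0:
        raise ValueError(f"ratio must be > 0, got {ratio}")
    return FoldClass(
        within_2fold=0.5 <= ratio <= 2.0,
        within_1p5fold=0.5 <= ratio <= 1.5,
        over_2fold=ratio > 2.0,
        under_0p5fold=ratio < 0.5,
    )


def afe(ratios: Iterable[float]) -> float:
    """Average fold error: the geometric mean of the ratios."""
    ratios = list(ratios)
    if not ratios:
        raise ValueError("ratios must be non-empty")
    if any(r <= 0 for r in ratios):
        raise ValueError("all ratios must be > 0")
    return 10.0 ** (sum(math.log10(r) for r in ratios) / len(ratios))


def summarize(
    pairs: Sequence[tuple[float, float]],
    species: str,
    method: str,
) -> EvaluationSummary:
    """Bin counts and AFE over (predicted, observed) clearance pairs."""
    if not pairs:
        raise ValueError("pairs must be non-empty")
    ratios = [fold_ratio(p, o) for p, o in pairs]
    classes = [classify_fold(r) for r in ratios]
    return EvaluationSummary(
        species=species,
        method=method,
        n=len(ratios),
        n_within_2fold=sum(c.within_2fold for c in classes),
        n_within_1p5fold=sum(c.within_1p5fold for c in classes),
        n_over=sum(c.over_2fold for c in classes),
        n_under=sum(c.under_0p5fold for c in classes),
        afe=afe(ratios),
    )


def check_dose_range(
    predicted_mgkg: float,
    range_low: float,
    range_high: float,
    mab_id: str = "",
) -> DoseRangeCheck:
    """Inclusive containment of a projected dose in the clinical dose range."""
    if range_low <= 0 or predicted_mgkg <= 0:
        raise ValueError("doses must be > 0")
    if range_low > range_high:
        raise ValueError(f"inverted range: {range_low} > {range_high}")
    return DoseRangeCheck(
        mab_id=mab_id,
        predicted_mgkg=predicted_mgkg,
        range_low=range_low,
        range_high=range_high,
        within=range_low <= predicted_mgkg <= range_high,
    )
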