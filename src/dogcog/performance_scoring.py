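"""Detection-dog performance scoring.

Turns four kinds of program records into a per-dog performance table:

* weekly training logs — seven behavioural categories each given a 0-3
  prevalence score per week; weeks reporting fewer than 3 training days are
  dropped; a dog's ratio score per category is total score / eligible weeks
  (higher = more problems);
* a duration adjustment — ratio scores regressed on the number of scored
  weeks, residuals sign-flipped so higher = better;
* ordinal weekly ratings (excellent/good/fair/poor) — summarized as the
  weight-summed percentage score bounded 0 (all poor) to 100 (all excellent);
* post-deployment evaluations — percent of pass/fail items passed per
  category.

Every measure in the assembled table carries an orientation flag
(larger-is-better or not); downstream association direction is interpreted
after orientation normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "LOG_CATEGORIES", "RATING_LEVELS", "TrainingLogWeek", "RatioScore",
    "OrdinalRatingSeries", "RatingWeights", "PerformanceTable",
    "score_training_logs", "adjust_for_duration", "weighted_ordinal_score",
    "percent_passed", "assemble_performance_table",
]

#: The seven behavioural categories coded from training records.
LOG_CATEGORIES = ("handling", "temperament", "motivation", "handler_dependence",
                  "odor_recognition", "odor_response", "false_responses")

RATING_LEVELS = ("excellent", "good", "fair", "poor")

#: A week needs at least this many reported training days to be scored.
MIN_DAYS_FOR_SCORING = 3


@dataclass
class TrainingLogWeek:
    """One dog-week of coded training-log prevalence scores (0-3 per category)."""

    dog_id: str
    week_index: int
    days_reported: int
    category_scores: Dict[str, int]

    def __post_init__(self) -> None:
        if set(self.category_scores) != set(LOG_CATEGORIES):
            raise ValueError(f"week for dog {self.dog_id}: category keys must be "
                             f"exactly {LOG_CATEGORIES}")
        for cat, s in self.category_scores.items():
            if s not in (0, 1, 2, 3):
                raise ValueError(f"prevalence score {s!r} out of range 0-3 "
                                 f"(dog {self.dog_id}, {cat})")
        if self.days_reported < 0:
            raise ValueError("days_reported must be non-negative")

    @property
    def eligible(self) -> bool:
        return self.days_reported >= MIN_DAYS_FOR_SCORING


@dataclass
class RatioScore:
    """Per dog and category: sum of weekly scores / number of scored weeks."""

    dog_id: str
    category: str
    ratio: float
    weeks_scored: int

    def __post_init__(self) -> None:
        if not 0 <= self.ratio <= 3:
            raise ValueError("ratio must lie in [0, 3]")


@dataclass
class OrdinalRatingSeries:
    dog_id: str
    ratings: List[str]

    def __post_init__(self) -> None:
        bad = [r for r in self.ratings if r not in RATING_LEVELS]
        if bad:
            raise ValueError(f"unknown rating token {bad[0]!r} for dog {self.dog_id}")


@dataclass
class RatingWeights:
    """Weights for the ordinal summary score; the printed defaults are
    excellent=1, good=0.66, fair=0.33, poor=0 (deliberately not 2/3 and 1/3)."""

    weights: Dict[str, float] = field(default_factory=lambda: {
        "excellent": 1.0, "good": 0.66, "fair": 0.33, "poor": 0.0})

    def __post_init__(self) -> None:
        if set(self.weights) != set(RATING_LEVELS):
            raise ValueError(f"weights must cover exactly {RATING_LEVELS}")
        vals = [self.weights[r] for r in RATING_LEVELS]
        if any(not 0 <= v <= 1 for v in vals):
            raise ValueError("weights must lie in [0, 1]")
        if any(a < b for a, b in zip(vals, vals[1:])):
            raise ValueError("weights must be monotone decreasing from "
                             "excellent to poor")


@dataclass
class PerformanceTable:
    """Wide dog x performance-measure table with availability and orientation.

    ``data`` holds NaN where a measure is unavailable for a dog.
    ``higher_is_better`` records each measure's orientation after any
    normalization flip performed at assembly.
    """

    data: pd.DataFrame
    higher_is_better: Dict[str, bool]

    def __post_init__(self) -> None:
        missing = set(self.data.columns) - set(self.higher_is_better)
        if missing:
            raise ValueError(f"measures without orientation: {sorted(missing)}")

    @property
    def availability(self) -> pd.DataFrame:
        return self.data.notna()


def score_training_logs(weeks: Sequence[TrainingLogWeek]) -> List[RatioScore]:
    """Per-dog, per-category ratio scores over eligible (>=3-day) weeks.

    Dogs with no eligible week are omitted (unavailable for this measure
    family).  Higher ratios mean more behavioural problems.
    """
    by_dog: Dict[str, List[TrainingLogWeek]] = {}
    for w in weeks:
        by_dog.setdefault(w.dog_id, []).append(w)
    out: List[RatioScore] = []
    for dog_id in by_dog:
        eligible = [w for w in by_dog[dog_id] if w.eligible]
        if not eligible:
            continue
        for cat in LOG_CATEGORIES:
            total = sum(w.category_scores[cat] for w in eligible)
            out.append(RatioScore(dog_id=dog_id, category=cat,
                                  ratio=total / len(eligible),
                                  weeks_scored=len(eligible)))
    return out


def adjust_for_duration(ratios: Sequence[float], weeks_scored: Sequence[int],
                        fallback_center: bool = False) -> np.ndarray:
    """Duration-adjusted performance: -1 x residual of ratio ~ weeks (OLS).

    Ratio scores correlate with how many weeks of records exist; regressing
    them on the week count and keeping sign-flipped residuals yields an
    adjusted score where higher = better, uncorrelated with record length,
    summing to zero.  Constant week counts leave the slope unidentifiable
    and raise, unless ``fallback_center`` asks for plain sign-flipped
    centering instead.
    """
    y = np.asarray(ratios, dtype=float)
    w = np.asarray(weeks_scored, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 dogs to adjust for duration")
    if np.all(w == w[0]):
        if fallback_center:
            return -(y - y.mean())
        raise ValueError("weeks_scored is constant; slope unidentifiable")
    X = np.column_stack([np.ones_like(w), w])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return -(y - X @ beta)


def weighted_ordinal_score(series: OrdinalRatingSeries,
                           weights: Optional[RatingWeights] = None) -> float:
    """Weight-summed percentage score of an ordinal rating series, in [0, 100]."""
    weights = weights or RatingWeights()
    if not series.ratings:
        raise ValueError(f"dog {series.dog_id}: empty rating series is unscorable")
    n = len(series.ratings)
    score = 0.0
    for level in RATING_LEVELS:
        pct = 100.0 * sum(r == level for r in series.ratings) / n
        score += pct * weights.weights[level]
    return float(score)


def percent_passed(items: Mapping[str, Tuple[int, int]]) -> Dict[str, float]:
    """Percent of pass/fail evaluation items passed, per category."""
    out = {}
    for cat, (passed, total) in items.items():
        if total < 1:
            raise ValueError(f"category {cat!r}: total items must be >= 1")
        if passed < 0 or passed > total:
            raise ValueError(f"category {cat!r}: passed must lie in [0, total]")
        out[cat] = 100.0 * passed / total
    return out


def assemble_performance_table(sources: Mapping[str, Mapping[str, float]],
                               orientation: Mapping[str, bool],
                               normalize_orientation: bool = False
                               ) -> PerformanceTable:
    """Merge scored measures into one wide table with availability mask.

    ``sources`` maps measure name -> {dog_id: value} (or an iterable of
    (dog_id, value) pairs, e.g. when one measure is assembled from several
    record batches); ``orientation`` maps measure name -> True when larger
    values mean better performance.  Conflicting duplicate values for one
    dog/measure are an error.  With ``normalize_orientation`` every
    lower-is-better measure is sign-flipped so that a "positive association"
    uniformly means higher cognition score goes with better performance.
    """
    cells: Dict[str, Dict[str, float]] = {}
    for measure, per_dog in sources.items():
        if measure not in orientation:
            raise ValueError(f"measure {measure!r} lacks an orientation flag")
        pairs = per_dog.items() if hasattr(per_dog, "items") else per_dog
        for dog_id, value in pairs:
            prev = cells.setdefault(measure, {})
            if dog_id in prev and prev[dog_id] != value:
                raise ValueError(f"conflicting values for dog {dog_id!r}, "
                                 f"measure {measure!r}")
            prev[dog_id] = float(value)
    df = pd.DataFrame(cells)
    df.index.name = "dog_id"
    df = df.sort_index()
    hib = {m: bool(orientation[m]) for m in df.columns}
    if normalize_orientation:
        for m in df.columns:
            if not hib[m]:
                df[m] = -df[m]
                hib[m] = True
    return PerformanceTable(data=df, higher_is_better=hib)
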