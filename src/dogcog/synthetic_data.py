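"""Synthetic working-dog cohorts with the latent structure the analyses assume.

Cognitive scores follow a latent-factor model (individual differences in dog
cognition load on several correlated-ability factors); a scalar latent
"quality" drives detection-dog performance records; assistance-dog outcomes
come from a logistic model on the cognitive measures with the intercept
calibrated to a target graduation base rate.  Default cohort conditions
mirror the study designs this package analyses: assistance modelling samples
of ~120 dogs at a 68% graduation rate (77% in the prospective sample), 11
battery measures, detection cohorts with seven weekly training-log
categories (mean 33 scored weeks per dog) and ordinal weekly ratings
(mean 97 records per dog).

All randomness flows from one root seed through named substreams, so each
stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .cohort_data import CognitiveMeasureMatrix, DogRecord
from .performance_scoring import (LOG_CATEGORIES, RATING_LEVELS, OrdinalRatingSeries,
                                  PerformanceTable, TrainingLogWeek)
import pandas as pd

__all__ = [
    "MeasureSpec", "PerformanceSpec", "SyntheticConfig", "SyntheticCohort",
    "assistance_config", "detection_config",
    "gen_cognitive_matrix", "gen_graduation_outcomes", "gen_training_logs",
    "gen_ordinal_series", "gen_performance_matrix", "inject_missingness",
    "gen_cohort",
]

#: The 11 measures retained for the short-format assistance battery.
ASSISTANCE_MEASURES = (
    "causal reasoning (visual)", "spatial transpositions", "inferential reasoning",
    "cylinder", "social referencing", "unsolvable task", "odor discrimination",
    "laterality: object manipulation", "laterality: first step", "arm pointing",
    "reward preference",
)


@dataclass
class MeasureSpec:
    """Generative spec for one cognitive measure: factor loadings + unique noise."""

    loadings: Tuple[float, ...]
    noise_sd: float = 0.7
    dist: str = "normal"  # or "lognormal" for skewed task scores


@dataclass
class PerformanceSpec:
    """Generative spec for one performance measure derived from latent quality."""

    loading: float = 0.7
    noise_sd: float = 0.7
    availability: float = 1.0
    higher_is_better: bool = True


@dataclass
class SyntheticConfig:
    n_dogs: int = 120
    n_factors: int = 3
    measure_spec: Dict[str, MeasureSpec] = field(default_factory=dict)
    outcome_coefficients: Dict[str, float] = field(default_factory=dict)
    target_base_rate: float = 0.68
    performance_spec: Dict[str, PerformanceSpec] = field(default_factory=dict)
    planted_effects: Dict[str, float] = field(default_factory=dict)
    missingness_rate: float = 0.0
    n_weeks_mean: float = 33.0
    n_rating_records_mean: float = 97.0
    cohort_label: str = "exploratory"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_base_rate < 1:
            raise ValueError("target_base_rate must lie in (0, 1)")
        if not 0 <= self.missingness_rate < 1:
            raise ValueError("missingness_rate must lie in [0, 1)")
        for spec in self.performance_spec.values():
            if not 0 <= spec.availability <= 1:
                raise ValueError("availability must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    """A fully cross-referenced simulated cohort, with ground-truth latents."""

    records: List[DogRecord]
    matrix: CognitiveMeasureMatrix
    outcomes: Optional[np.ndarray]
    factors: np.ndarray
    quality: np.ndarray
    training_logs: List[TrainingLogWeek]
    rating_series: List[OrdinalRatingSeries]
    performance: Optional[PerformanceTable]


# substream indices off the root seed
_STREAMS = {"factors": 0, "noise": 1, "quality": 2, "outcome": 3,
            "performance": 4, "logs": 5, "ordinal": 6, "missing": 7,
            "roster": 8}


def _rng(seed: int, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(seed) % (2 ** 31),
                                spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


def _default_measure_spec(names: Sequence[str], n_factors: int) -> Dict[str, MeasureSpec]:
    """Simple structure: each measure loads 0.7 on one factor, cycling."""
    spec = {}
    for i, name in enumerate(names):
        loadings = [0.0] * n_factors
        loadings[i % n_factors] = 0.7
        spec[name] = MeasureSpec(loadings=tuple(loadings), noise_sd=0.7)
    return spec


def assistance_config(n_dogs: int = 120, target_base_rate: float = 0.68,
                      outcome_coefficients: Optional[Dict[str, float]] = None,
                      missingness_rate: float = 0.0, seed: int = 0,
                      cohort_label: str = "exploratory") -> SyntheticConfig:
    """An assistance-dog cohort: 11 battery measures, 3 latent factors."""
    return SyntheticConfig(
        n_dogs=n_dogs, n_factors=3,
        measure_spec=_default_measure_spec(ASSISTANCE_MEASURES, 3),
        outcome_coefficients=dict(outcome_coefficients or {}),
        target_base_rate=target_base_rate, missingness_rate=missingness_rate,
        cohort_label=cohort_label, seed=seed)


def detection_config(n_dogs: int = 150, n_measures: int = 12,
                     planted_effects: Optional[Dict[str, float]] = None,
                     n_performance: int = 8, availability: float = 1.0,
                     missingness_rate: float = 0.0, seed: int = 0,
                     cohort_label: str = "exploratory") -> SyntheticConfig:
    """A detection-dog cohort: generic measures, quality-driven performance."""
    names = [f"measure_{i:02d}" for i in range(n_measures)]
    perf = {f"performance_{i:02d}": PerformanceSpec(availability=availability)
            for i in range(n_performance)}
    return SyntheticConfig(
        n_dogs=n_dogs, n_factors=3,
        measure_spec=_default_measure_spec(names, 3),
        planted_effects=dict(planted_effects or {}),
        performance_spec=perf, missingness_rate=missingness_rate,
        cohort_label=cohort_label, seed=seed)


def gen_cognitive_matrix(config: SyntheticConfig,
                         quality: Optional[np.ndarray] = None
                         ) -> Tuple[CognitiveMeasureMatrix, np.ndarray]:
    """Draw dogs x measures scores from the factor model; returns (matrix, factors).

    A measure with a planted effect rho is blended with the latent quality so
    its correlation with quality converges to rho while keeping unit variance.
    """
    if not config.measure_spec:
        raise ValueError("config.measure_spec is empty")
    names = list(config.measure_spec)
    load = np.array([config.measure_spec[m].loadings for m in names], dtype=float)
    if load.shape[1] != config.n_factors:
        raise ValueError("loading length does not match n_factors")
    if np.linalg.matrix_rank(load) == 0 and np.any(load != 0):
        raise ValueError("degenerate loading matrix")
    rng_f = _rng(config.seed, "factors")
    rng_e = _rng(config.seed, "noise")
    F = rng_f.standard_normal((config.n_dogs, config.n_factors))
    values = np.empty((config.n_dogs, len(names)))
    for j, m in enumerate(names):
        spec = config.measure_spec[m]
        base = F @ load[j] + spec.noise_sd * rng_e.standard_normal(config.n_dogs)
        base_sd = float(np.sqrt(np.sum(load[j] ** 2) + spec.noise_sd ** 2))
        rho = float(config.planted_effects.get(m, 0.0))
        if rho != 0.0:
            if quality is None:
                raise ValueError("planted_effects require a quality vector")
            values[:, j] = rho * quality + np.sqrt(max(0.0, 1 - rho ** 2)) * base / base_sd
        else:
            values[:, j] = base
        if spec.dist == "lognormal":
            values[:, j] = np.exp(values[:, j])
    ids = [f"dog{i:04d}" for i in range(config.n_dogs)]
    matrix = CognitiveMeasureMatrix(ids, names, values,
                                    np.zeros(values.shape, dtype=bool))
    return matrix, F


def gen_graduation_outcomes(matrix: CognitiveMeasureMatrix,
                            outcome_coefficients: Dict[str, float],
                            target_base_rate: float,
                            seed: int = 0) -> np.ndarray:
    """Binary graduate(1)/release(0) labels from a calibrated logistic model.

    The linear predictor uses standardized measures with the given log-odds
    coefficients; the intercept is solved so the expected graduation rate
    equals the target (within 1e-6 of the root, hence well within 0.01).
    """
    unknown = set(outcome_coefficients) - set(matrix.measure_names)
    if unknown:
        raise ValueError(f"coefficients reference unknown measures: {sorted(unknown)}")
    X = matrix.values
    eta = np.zeros(matrix.n_dogs)
    for m, beta in outcome_coefficients.items():
        col = X[:, matrix.measure_names.index(m)]
        eta += beta * (col - col.mean()) / (col.std(ddof=1) or 1.0)

    def expected(c):
        return float(np.mean(expit(c + eta))) - target_base_rate

    lo, hi = -30.0, 30.0
    if expected(lo) > 0 or expected(hi) < 0:
        raise ValueError("target base rate unreachable given coefficients")
    c = brentq(expected, lo, hi, xtol=1e-10)
    rng = _rng(seed, "outcome")
    return (rng.random(matrix.n_dogs) < expit(c + eta)).astype(int)


def gen_quality(config: SyntheticConfig) -> np.ndarray:
    """Latent detection-dog quality, one standard-normal scalar per dog."""
    return _rng(config.seed, "quality").standard_normal(config.n_dogs)


def gen_training_logs(config: SyntheticConfig, quality: np.ndarray
                      ) -> List[TrainingLogWeek]:
    """Weekly 0-3 prevalence scores whose severity decreases with quality.

    Scores follow an ordered-logit over {0,1,2,3} with cutpoints
    (-0.8, -2.0, -3.2) on a -quality scale; days_reported is uniform on 1-5
    so some weeks fall under the 3-day scoring floor.
    """
    rng = _rng(config.seed, "logs")
    cut = np.array([-0.8, -2.0, -3.2])
    weeks: List[TrainingLogWeek] = []
    for i in range(config.n_dogs):
        n_weeks = max(1, int(rng.poisson(config.n_weeks_mean)))
        p_ge = expit(cut - quality[i])  # P(score >= 1, 2, 3)
        for w in range(n_weeks):
            days = int(rng.integers(1, 6))
            scores = {}
            for cat in LOG_CATEGORIES:
                u = rng.random()
                scores[cat] = int(np.sum(u < p_ge))
            weeks.append(TrainingLogWeek(dog_id=f"dog{i:04d}", week_index=w,
                                         days_reported=days, category_scores=scores))
    return weeks


def gen_ordinal_series(config: SyntheticConfig, quality: np.ndarray
                       ) -> List[OrdinalRatingSeries]:
    """Weekly excellent/good/fair/poor ratings from an ordered logit on quality."""
    rng = _rng(config.seed, "ordinal")
    cut = np.array([1.2, 0.0, -1.2])  # thresholds for excellent, >=good, >=fair
    series: List[OrdinalRatingSeries] = []
    for i in range(config.n_dogs):
        n = max(1, int(rng.poisson(config.n_rating_records_mean)))
        p_ge = expit(quality[i] - cut)  # P(excellent), P(>=good), P(>=fair)
        ratings = []
        for _ in range(n):
            u = rng.random()
            level = int(np.sum(u < p_ge))  # 3=excellent ... 0=poor
            ratings.append(RATING_LEVELS[3 - level])
        series.append(OrdinalRatingSeries(dog_id=f"dog{i:04d}", ratings=ratings))
    return series


def gen_performance_matrix(config: SyntheticConfig, quality: np.ndarray
                           ) -> PerformanceTable:
    """Continuous performance measures loading on quality, with availability gaps."""
    rng = _rng(config.seed, "performance")
    ids = [f"dog{i:04d}" for i in range(config.n_dogs)]
    data = {}
    orientation = {}
    for name, spec in config.performance_spec.items():
        v = spec.loading * quality + spec.noise_sd * rng.standard_normal(config.n_dogs)
        if not spec.higher_is_better:
            v = -v
        avail = rng.random(config.n_dogs) < spec.availability
        v = np.where(avail, v, np.nan)
        data[name] = v
        orientation[name] = spec.higher_is_better
    df = pd.DataFrame(data, index=pd.Index(ids, name="dog_id"))
    return PerformanceTable(data=df, higher_is_better=orientation)


def inject_missingness(matrix: CognitiveMeasureMatrix, rate: float, seed: int = 0
                       ) -> CognitiveMeasureMatrix:
    """Mask each observed cell independently with the given probability."""
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    out = matrix.copy()
    if rate == 0:
        return out
    rng = _rng(seed, "missing")
    hit = (rng.random(out.values.shape) < rate) & ~out.missing_mask
    out.values[hit] = np.nan
    out.missing_mask |= hit
    return out


def gen_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a complete cohort: roster, scores, outcomes, and records."""
    quality = gen_quality(config)
    matrix, factors = gen_cognitive_matrix(config, quality=quality)
    outcomes = None
    if config.outcome_coefficients or not config.performance_spec:
        outcomes = gen_graduation_outcomes(matrix, config.outcome_coefficients,
                                           config.target_base_rate, seed=config.seed)
    rng = _rng(config.seed, "roster")
    records = []
    for i in range(config.n_dogs):
        records.append(DogRecord(
            dog_id=f"dog{i:04d}",
            sex="female" if rng.random() < 0.6 else "male",
            breed="labrador retriever",
            age_years=float(max(0.5, rng.normal(2.0, 0.2))),
            cohort=config.cohort_label,
            status_flags=frozenset(),
            outcome=(None if outcomes is None else
                     ("graduate" if outcomes[i] else "release"))))
    matrix = inject_missingness(matrix, config.missingness_rate, seed=config.seed)
    logs = gen_training_logs(config, quality) if config.performance_spec else []
    ratings = gen_ordinal_series(config, quality) if config.performance_spec else []
    performance = gen_performance_matrix(config, quality) if config.performance_spec else None
    return SyntheticCohort(records=records, matrix=matrix, outcomes=outcomes,
                           factors=factors, quality=quality, training_logs=logs,
                           rating_series=ratings, performance=performance)
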