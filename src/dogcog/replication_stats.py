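"""Replication-panel statistics and inter-rater reliability.

The replication design regresses each performance outcome on each cognitive
predictor with both variables z-scored, collects the standardized slopes
(beta; equal to the Pearson correlation for a single predictor), and runs a
one-tailed one-sample t-test of each predictor's beta panel against zero in
the direction hypothesized from the exploratory screen.  A panel mean
opposing its hypothesized direction yields a one-tailed p above 0.5.

Inter-rater reliability uses Cohen's kappa for discrete codes and the
Pearson correlation for continuous scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .preprocess import zscore

__all__ = [
    "BetaRecord", "DirectionalTestResult", "ReliabilityResult",
    "standardized_beta", "beta_panel_test", "cohen_kappa", "pearson_r",
]


@dataclass
class BetaRecord:
    """Standardized slope of one outcome on one predictor (pairwise-complete)."""

    predictor: str
    outcome: str
    beta: float
    n_used: int

    def __post_init__(self) -> None:
        if self.n_used < 3:
            raise ValueError("beta requires n_used >= 3")
        if abs(self.beta) > 1 + 1e-8:
            raise ValueError("single-predictor standardized beta must lie in [-1, 1]")


@dataclass
class DirectionalTestResult:
    """One-tailed one-sample t-test summary of a predictor's beta panel."""

    predictor: str
    mean_beta: float
    sem_beta: float
    t: float
    df: int
    p_one_tailed: float
    hypothesized_direction: str

    def __post_init__(self) -> None:
        if self.hypothesized_direction not in ("positive", "negative"):
            raise ValueError("hypothesized_direction must be positive or negative")
        if not 0 <= self.p_one_tailed <= 1:
            raise ValueError("p must lie in [0, 1]")


@dataclass
class ReliabilityResult:
    measure: str
    statistic_kind: str  # cohen_kappa | pearson_r
    value: float
    n_items: int


def standardized_beta(x: Sequence[float], y: Sequence[float],
                      predictor: str = "", outcome: str = "") -> BetaRecord:
    """Least-squares slope of z(y) on z(x) over pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    xo, yo = x[keep], y[keep]
    if xo.size < 3:
        raise ValueError("need at least 3 pairwise-complete observations")
    if np.all(xo == xo[0]) or np.all(yo == yo[0]):
        raise ValueError("zero variance in predictor or outcome")
    zx, zy = zscore(xo), zscore(yo)
    beta = float(np.dot(zx, zy) / np.dot(zx, zx))
    return BetaRecord(predictor=predictor, outcome=outcome, beta=beta,
                      n_used=int(xo.size))


def beta_panel_test(betas: Sequence[float], direction: str, predictor: str = ""
                    ) -> DirectionalTestResult:
    """One-tailed one-sample t-test of a beta panel against a zero mean.

    t = mean / SEM with df = n - 1; p is the tail probability in the
    hypothesized direction, so an opposing mean gives p > 0.5.
    """
    b = np.asarray(betas, dtype=float)
    if b.size < 2:
        raise ValueError("need at least 2 betas")
    sem = float(stats.sem(b))
    if sem == 0:
        raise ValueError("zero standard error in the beta panel")
    mean = float(b.mean())
    t = mean / sem
    df = b.size - 1
    if direction == "positive":
        p = float(stats.t.sf(t, df))
    elif direction == "negative":
        p = float(stats.t.cdf(t, df))
    else:
        raise ValueError("direction must be 'positive' or 'negative'")
    return DirectionalTestResult(predictor=predictor, mean_beta=mean,
                                 sem_beta=sem, t=float(t), df=df,
                                 p_one_tailed=p, hypothesized_direction=direction)


def cohen_kappa(ratings_a: Sequence, ratings_b: Sequence, measure: str = ""
                ) -> ReliabilityResult:
    """Cohen's kappa with marginal-product chance agreement.

    Two constant, identical raters leave chance agreement at 1; kappa is
    then defined as 1 by convention (logged), since agreement is perfect.
    """
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("rating sequences must have equal length >= 2")
    if len(set(a)) == 1 and a == b:
        warnings.warn("both raters constant and identical; kappa defined as 1")
        return ReliabilityResult(measure, "cohen_kappa", 1.0, len(a))
    value = float(cohen_kappa_score(a, b))
    return ReliabilityResult(measure, "cohen_kappa", value, len(a))


def pearson_r(x: Sequence[float], y: Sequence[float], measure: str = ""
              ) -> ReliabilityResult:
    """Product-moment correlation over pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    xo, yo = x[keep], y[keep]
    if xo.size < 3:
        raise ValueError("need at least 3 pairwise-complete observations")
    if np.all(xo == xo[0]) or np.all(yo == yo[0]):
        raise ValueError("zero variance")
    r = float(stats.pearsonr(xo, yo).statistic)
    return ReliabilityResult(measure, "pearson_r", r, int(xo.size))
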