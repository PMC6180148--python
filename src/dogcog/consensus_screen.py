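"""Directional consensus screening across heterogeneous performance outcomes.

With many cognition x performance tests at an uncorrected alpha, false
positives are expected — but their directions should be random.  Each
significant association is annotated +1 (higher cognition with better
performance), -1 (worse), or 0 (significant 3-group omnibus with
non-monotone group means), and the per-measure sum of annotations is the
aggregate consensus score.  A one-sample t-test of the aggregates against 0
checks the sign-randomness assumption, and measures whose |aggregate|
clears a threshold are retained for a short-format battery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "AssociationRecord", "AggregateScoreRow", "ConsensusSummary",
    "test_association", "build_aggregate_table", "consensus_null_test",
    "select_short_battery",
]

ALPHA_DEFAULT = 0.05


@dataclass
class AssociationRecord:
    """One cognition-measure x performance-measure association test."""

    cognitive_measure: str
    performance_measure: str
    test: str                      # two_sample_t | anova_3group
    p_value: float
    direction: str                 # positive | negative | neutral
    significant: bool
    available: bool = True

    def __post_init__(self) -> None:
        if self.test not in ("two_sample_t", "anova_3group"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.direction not in ("positive", "negative", "neutral"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction == "neutral" and self.test == "two_sample_t" and self.significant:
            raise ValueError("two-group tests cannot yield a neutral direction")


@dataclass
class AggregateScoreRow:
    """Counts of significant directional associations for one cognitive measure."""

    cognitive_measure: str
    total: int
    n_negative: int
    n_neutral: int
    n_positive: int
    aggregate: int

    def __post_init__(self) -> None:
        if self.total != self.n_positive + self.n_negative + self.n_neutral:
            raise ValueError("total must equal positive + negative + neutral")
        if self.aggregate != self.n_positive - self.n_negative:
            raise ValueError("aggregate must equal n_positive - n_negative")

    @classmethod
    def from_counts(cls, cognitive_measure: str, total: int, n_negative: int,
                    n_neutral: int, n_positive: int) -> "AggregateScoreRow":
        """Build a row from association counts, deriving the aggregate score."""
        return cls(cognitive_measure=cognitive_measure, total=int(total),
                   n_negative=int(n_negative), n_neutral=int(n_neutral),
                   n_positive=int(n_positive),
                   aggregate=int(n_positive) - int(n_negative))


@dataclass
class ConsensusSummary:
    """One-sample test of the aggregate scores against a zero mean."""

    mean_aggregate: float
    sem_aggregate: float
    t: float
    df: int
    p: float
    mean_associations: float
    sem_associations: float


def _monotone_direction(means: Sequence[float]) -> str:
    """Direction from ordered group means: weakly monotone (at most one tie
    junction) and overall increasing/decreasing -> positive/negative; else neutral."""
    diffs = np.diff(np.asarray(means, dtype=float))
    if means[-1] > means[0] and np.all(diffs >= 0):
        return "positive"
    if means[-1] < means[0] and np.all(diffs <= 0):
        return "negative"
    return "neutral"


def test_association(cog_scores: Sequence[float], categories: Sequence,
                     cognitive_measure: str = "", performance_measure: str = "",
                     alpha: float = ALPHA_DEFAULT, welch: bool = True
                     ) -> AssociationRecord:
    """Test one cognition measure against one discretized performance measure.

    Two categories (below/above): two-sample t-test (Welch by default) of the
    cognition scores between performance groups; direction is positive when
    the above-average-performance group has the higher cognition mean.
    Three categories (below/average/above): one-way ANOVA; a significant
    omnibus with monotone ordered group means takes the sign of top minus
    bottom, otherwise it is annotated neutral.

    Dogs missing either variable are dropped pairwise; a category emptied
    (<2 observations) marks the record unavailable rather than raising.
    """
    x = np.asarray(cog_scores, dtype=float)
    cats = np.asarray(categories, dtype=object)
    keep = np.isfinite(x) & np.array([c is not None for c in cats])
    x, cats = x[keep], cats[keep]
    present = [c for c in ("below", "average", "above") if c in set(cats)]
    levels = ("below", "above") if "average" not in set(cats) else \
             ("below", "average", "above")
    test = "two_sample_t" if len(levels) == 2 else "anova_3group"
    groups = [x[cats == c] for c in levels]
    if any(len(g) < 2 for g in groups):
        return AssociationRecord(cognitive_measure, performance_measure, test,
                                 p_value=float("nan"), direction="neutral",
                                 significant=False, available=False)

    if test == "two_sample_t":
        if all(np.all(g == g[0]) for g in groups) and groups[0][0] == groups[1][0]:
            p = 1.0
        else:
            p = float(stats.ttest_ind(groups[1], groups[0],
                                      equal_var=not welch).pvalue)
        direction = "positive" if groups[1].mean() > groups[0].mean() else "negative"
        if groups[1].mean() == groups[0].mean():
            direction = "positive"  # degenerate tie; never significant
    else:
        if all(np.all(g == groups[0][0]) for g in groups):
            p = 1.0
        else:
            p = float(stats.f_oneway(*groups).pvalue)
        direction = _monotone_direction([g.mean() for g in groups])
    significant = bool(np.isfinite(p) and p < alpha)
    return AssociationRecord(cognitive_measure, performance_measure, test,
                             p_value=p, direction=direction,
                             significant=significant)


def build_aggregate_table(records: Iterable[AssociationRecord],
                          alpha: float = ALPHA_DEFAULT,
                          measures: Optional[Sequence[str]] = None
                          ) -> List[AggregateScoreRow]:
    """Aggregate significant associations into one consensus row per cognitive measure.

    Only available, significant records contribute; ``measures`` fixes the
    row universe (so measures with no significant association still appear
    with zero counts), defaulting to the measures present in ``records``.
    """
    records = list(records)
    seen = set()
    for r in records:
        key = (r.cognitive_measure, r.performance_measure)
        if key in seen:
            raise ValueError(f"duplicate association record for {key}")
        seen.add(key)
    if measures is None:
        measures = list(dict.fromkeys(r.cognitive_measure for r in records))
    counts = {m: {"positive": 0, "negative": 0, "neutral": 0} for m in measures}
    for r in records:
        if not r.available or not r.significant:
            continue
        if not (np.isfinite(r.p_value) and r.p_value < alpha):
            continue
        counts[r.cognitive_measure][r.direction] += 1
    rows = []
    for m in measures:
        c = counts[m]
        rows.append(AggregateScoreRow.from_counts(
            m, total=c["positive"] + c["negative"] + c["neutral"],
            n_negative=c["negative"], n_neutral=c["neutral"],
            n_positive=c["positive"]))
    return rows


def consensus_null_test(rows: Sequence[AggregateScoreRow]) -> ConsensusSummary:
    """Two-tailed one-sample t-test of aggregate scores against 0.

    Under the screen's working assumption — false positives equally likely
    in either direction — the aggregates should centre on zero.  Also
    summarizes the per-measure association counts (mean +/- SEM).
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 aggregate rows")
    agg = np.array([r.aggregate for r in rows], dtype=float)
    tot = np.array([r.total for r in rows], dtype=float)
    if np.all(agg == agg[0]):
        raise ValueError("aggregate scores have zero variance")
    res = stats.ttest_1samp(agg, 0.0)
    return ConsensusSummary(
        mean_aggregate=float(agg.mean()), sem_aggregate=float(stats.sem(agg)),
        t=float(res.statistic), df=len(agg) - 1, p=float(res.pvalue),
        mean_associations=float(tot.mean()), sem_associations=float(stats.sem(tot)))


def select_short_battery(rows: Sequence[AggregateScoreRow], threshold: int = 3,
                         manual_includes: Sequence[str] = ()
                         ) -> List[Tuple[str, str]]:
    """Measures retained for a short battery: |aggregate| >= threshold, plus
    manually included measures (flagged as such).  Returns (measure, reason)."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    known = {r.cognitive_measure for r in rows}
    unknown = set(manual_includes) - known
    if unknown:
        raise ValueError(f"manual includes name unknown measures: {sorted(unknown)}")
    selected: List[Tuple[str, str]] = []
    for r in rows:
        if abs(r.aggregate) >= threshold:
            selected.append((r.cognitive_measure,
                             f"|aggregate| = {abs(r.aggregate)} >= {threshold}"))
    chosen = {m for m, _ in selected}
    for m in manual_includes:
        if m not in chosen:
            selected.append((m, "manual include"))
    return selected
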