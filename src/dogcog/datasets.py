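"""Bundled worked-example data.

Small published summary tables from a two-population working-dog cognition
study, used by the documentation examples and the desk-scale reproduction
checks.  These are aggregate counts and summary accuracies only — no
dog-level data.
"""

from __future__ import annotations

from typing import Dict, List

import pandas as pd

from .consensus_screen import AggregateScoreRow

__all__ = [
    "detection_consensus_counts", "detection_consensus_rows",
    "assistance_upper_quartile_accuracies", "assistance_exclusion_counts",
    "assistance_outcome_split",
]

# Per cognitive measure: (total, negative, neutral, positive) counts of
# significant associations with detection-dog performance measures from the
# exploratory consensus screen of a 222-dog detection cohort.
_CONSENSUS_COUNTS = [
    ("odor discrimination", 5, 0, 0, 5),
    ("marker cue", 5, 0, 0, 5),
    ("causal reasoning (visual)", 4, 0, 0, 4),
    ("arm pointing", 4, 0, 0, 4),
    ("memory - distraction", 5, 1, 0, 4),
    ("working memory", 5, 1, 0, 4),
    ("odor control trials", 2, 0, 0, 2),
    ("inferential reasoning", 2, 0, 1, 1),
    ("affect discrimination", 2, 0, 1, 1),
    ("spatial transpositions", 3, 0, 2, 1),
    ("laterality: first step", 1, 0, 0, 1),
    ("causal reasoning (auditory)", 2, 1, 0, 1),
    ("reaching", 2, 1, 0, 1),
    ("perspective-taking (obey command)", 2, 1, 0, 1),
    ("cylinder", 0, 0, 0, 0),
    ("retrieval", 1, 0, 1, 0),
    ("rotation", 2, 1, 0, 1),
    ("unsolvable task (look at experimenter)", 3, 2, 0, 1),
    ("spatial perseveration", 5, 3, 0, 2),
    ("perspective-taking (steal food)", 1, 1, 0, 0),
    ("transparent obstacle", 10, 5, 1, 4),
    ("detour navigation", 1, 1, 0, 0),
    ("social referencing", 1, 1, 0, 0),
    ("gaze direction", 1, 1, 0, 0),
    ("sensory bias", 3, 2, 0, 1),
    ("visual discrimination", 6, 3, 1, 2),
    ("contagious yawning", 6, 4, 0, 2),
    ("laterality: object manipulation", 2, 2, 0, 0),
    ("unsolvable task (manipulate container)", 6, 6, 0, 0),
]


def detection_consensus_counts() -> pd.DataFrame:
    """Association counts (total/negative/neutral/positive) per cognitive measure."""
    return pd.DataFrame(_CONSENSUS_COUNTS,
                        columns=["measure", "total", "n_negative", "n_neutral",
                                 "n_positive"])


def detection_consensus_rows() -> List[AggregateScoreRow]:
    """The same counts as AggregateScoreRow objects (aggregates derived, not stored)."""
    return [AggregateScoreRow.from_counts(m, t, neg, neu, pos)
            for m, t, neg, neu, pos in _CONSENSUS_COUNTS]


def assistance_upper_quartile_accuracies() -> Dict[str, float]:
    """Prospective-sample accuracy within the top predicted-probability quartile,
    per model family, from the assistance-dog prediction study."""
    return {"LDA": 0.90, "GLM": 0.87, "RR": 0.83, "PLS": 0.83,
            "NB": 0.87, "MARS": 0.83, "KNN": 0.83, "RF": 0.90}


def assistance_exclusion_counts() -> Dict[str, Dict[str, int]]:
    """Printed exclusion accounting for the two assistance-dog cohorts."""
    return {
        "exploratory": {"initial_n": 164, "hearing_transfer": 21,
                        "aborted_over_2": 24, "medical_release": 8},
        "prediction": {"initial_n": 180, "status_excluded": 33,
                       "missing_over_2_predictors": 26},
    }


def assistance_outcome_split() -> Dict[str, int]:
    """Graduate/release counts in the exploratory assistance sample."""
    return {"graduate": 76, "release": 35}
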