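"""Cohort data model: dog rosters, cognitive score matrices, and exclusion accounting.

Input files are plain CSV/TSV with a header row.  A roster file carries one
row per dog (identity, demographics, program status, binary training
outcome); a scores file carries one row per dog and one column per cognitive
measure.  Measure names are validated against a controlled vocabulary — the
25 tasks of the Dog Cognition Test Battery plus their named sub-measures —
so that typos become errors rather than silently dropped columns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DCTB_TASKS",
    "DCTB_VOCABULARY",
    "DogRecord",
    "CognitiveMeasureMatrix",
    "ExclusionRule",
    "ExclusionReport",
    "load_cohort",
    "save_cohort",
    "apply_exclusions",
    "missingness_summary",
]

#: The 25 tasks of the Dog Cognition Test Battery.
DCTB_TASKS = (
    "affect discrimination",
    "arm pointing",
    "causal reasoning",
    "contagious yawning",
    "cylinder",
    "detour navigation",
    "gaze direction",
    "hiding-finding",
    "inferential reasoning",
    "laterality: first step",
    "laterality: object manipulation",
    "marker cue",
    "memory - distraction",
    "odor control trials",
    "odor discrimination",
    "perspective-taking",
    "reaching",
    "retrieval",
    "reward preference",
    "rotation",
    "sensory bias",
    "social referencing",
    "spatial perseveration",
    "spatial transpositions",
    "transparent obstacle",
    "unsolvable task",
    "visual discrimination",
    "working memory",
)

#: Named sub-measures that appear in analyses alongside the task names.
_SUB_MEASURES = (
    "causal reasoning (visual)",
    "causal reasoning (auditory)",
    "memory - distraction",
    "memory—distraction",
    "perspective-taking (obey command)",
    "perspective-taking (steal food)",
    "spatial transpositions (one-cross)",
    "unsolvable task (look at experimenter)",
    "unsolvable task (manipulate container)",
)

DCTB_VOCABULARY = tuple(sorted(set(DCTB_TASKS) | set(_SUB_MEASURES)))

_SEXES = ("female", "male")
_COHORTS = ("exploratory", "prediction", "replication")
_STATUS_FLAGS = (
    "hearing_transfer",
    "medical_release",
    "other_program",
    "in_training",
    "behavioral_release",
    "serviceable",
    "unserviceable_behavioral",
)
_OUTCOMES = ("graduate", "release")

#: Tokens accepted as "missing" in score cells (empty cell written on save).
MISSING_TOKENS = ("", "NA")


def normalize_measure_name(name: str) -> str:
    """Lower-case and whitespace-collapse a measure name for vocabulary lookup."""
    return " ".join(str(name).strip().lower().split())


@dataclass
class DogRecord:
    """One dog in a cohort roster.

    ``aborted_tasks`` counts battery tasks the dog declined to complete; it
    feeds the max-aborted-tasks exclusion rule.  ``outcome`` is only present
    for assistance-dog cohorts (graduate/release).
    """

    dog_id: str
    sex: str
    breed: str
    age_years: float
    cohort: str
    status_flags: frozenset = field(default_factory=frozenset)
    outcome: Optional[str] = None
    aborted_tasks: int = 0

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"unknown sex {self.sex!r} for dog {self.dog_id}")
        if self.cohort not in _COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r} for dog {self.dog_id}")
        if not self.age_years > 0:
            raise ValueError(f"age_years must be positive (dog {self.dog_id})")
        unknown = set(self.status_flags) - set(_STATUS_FLAGS)
        if unknown:
            raise ValueError(f"unknown status flags {sorted(unknown)} for dog {self.dog_id}")
        if self.outcome is not None and self.outcome not in _OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r} for dog {self.dog_id}")
        if self.aborted_tasks < 0:
            raise ValueError("aborted_tasks must be non-negative")


@dataclass
class CognitiveMeasureMatrix:
    """Dogs x cognitive measures, with an explicit missingness mask.

    ``values`` holds NaN exactly where ``missing_mask`` is True, so a cell is
    either a finite number or flagged missing, never both.
    """

    dog_ids: list
    measure_names: list
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, m = len(self.dog_ids), len(self.measure_names)
        if self.values.shape != (n, m) or self.missing_mask.shape != (n, m):
            raise ValueError("values/mask shape does not match dog_ids x measure_names")
        if len(set(self.dog_ids)) != n:
            raise ValueError("duplicate dog_id in matrix")
        if len(set(self.measure_names)) != m:
            raise ValueError("duplicate measure name in matrix")
        finite = np.isfinite(self.values)
        if np.any(finite & self.missing_mask):
            raise ValueError("cell flagged missing but holds a finite value")
        if np.any(~finite & ~self.missing_mask):
            raise ValueError("non-finite cell not flagged missing")

    @property
    def n_dogs(self) -> int:
        return len(self.dog_ids)

    @property
    def n_measures(self) -> int:
        return len(self.measure_names)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.dog_ids, name="dog_id"),
                            columns=self.measure_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CognitiveMeasureMatrix":
        values = df.to_numpy(dtype=float)
        return cls(list(df.index), list(df.columns), values, ~np.isfinite(values))

    def copy(self) -> "CognitiveMeasureMatrix":
        return CognitiveMeasureMatrix(list(self.dog_ids), list(self.measure_names),
                                      self.values.copy(), self.missing_mask.copy())

    def subset_dogs(self, keep: Sequence[int]) -> "CognitiveMeasureMatrix":
        keep = list(keep)
        return CognitiveMeasureMatrix(
            [self.dog_ids[i] for i in keep], list(self.measure_names),
            self.values[keep], self.missing_mask[keep])


@dataclass
class ExclusionRule:
    """One cohort-exclusion rule, applied in listed order; first match wins.

    kinds:
      status_flag          — remove dogs carrying any flag in ``parameter`` (a set)
      max_aborted_tasks    — remove dogs with aborted_tasks > ``parameter``
      max_missing_predictors — remove dogs missing > ``parameter`` measures
    """

    name: str
    kind: str
    parameter: object

    _KINDS = ("status_flag", "max_aborted_tasks", "max_missing_predictors")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown exclusion kind {self.kind!r}")
        if self.kind == "status_flag":
            flags = frozenset(self.parameter) if not isinstance(self.parameter, str) \
                else frozenset([self.parameter])
            unknown = flags - set(_STATUS_FLAGS)
            if unknown:
                raise ValueError(f"rule {self.name!r} references unknown status flags "
                                 f"{sorted(unknown)}")
            self.parameter = flags
        else:
            if int(self.parameter) < 0:
                raise ValueError(f"rule {self.name!r} parameter must be non-negative")
            self.parameter = int(self.parameter)


@dataclass
class ExclusionReport:
    """Accounting of an exclusion pass: initial_n = final_n + sum(removed)."""

    initial_n: int
    removed: dict
    final_n: int

    def __post_init__(self) -> None:
        if self.final_n < 0:
            raise ValueError("final_n < 0")
        if self.initial_n != self.final_n + sum(self.removed.values()):
            raise ValueError("exclusion accounting does not reconcile")


def _read_table(path, delimiter: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)


def load_cohort(roster_path, scores_path, schema: Optional[Mapping[str, str]] = None,
                delimiter: str = ",", missing_tokens: Sequence[str] = MISSING_TOKENS,
                vocabulary: Optional[Sequence[str]] = DCTB_VOCABULARY):
    """Read a roster CSV and a scores CSV into aligned records and a matrix.

    ``schema`` optionally remaps roster column names (logical -> file column).
    The score matrix rows are reordered to match the roster.  Unknown measure
    columns are an error when ``vocabulary`` is given; pass ``vocabulary=None``
    to accept arbitrary measure names (e.g. simulated cohorts).
    """
    schema = dict(schema or {})
    col = lambda name: schema.get(name, name)
    roster = _read_table(roster_path, delimiter)

    ids = roster[col("dog_id")].tolist()
    dup = pd.Series(ids)[pd.Series(ids).duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate dog_id in roster: {dup.iloc[0]!r}")

    records = []
    for _, row in roster.iterrows():
        flags_raw = row.get(col("status_flags"), "")
        flags = frozenset(f for f in str(flags_raw).split(";") if f)
        outcome = row.get(col("outcome"), "") or None
        aborted = row.get(col("aborted_tasks"), "")
        records.append(DogRecord(
            dog_id=row[col("dog_id")], sex=row[col("sex")], breed=row[col("breed")],
            age_years=float(row[col("age_years")]), cohort=row[col("cohort")],
            status_flags=flags, outcome=outcome,
            aborted_tasks=int(aborted) if aborted not in ("", None) else 0))

    scores = _read_table(scores_path, delimiter)
    if scores["dog_id"].duplicated().any():
        bad = scores["dog_id"][scores["dog_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate dog_id in scores file: {bad!r}")
    scores = scores.set_index("dog_id")
    missing_ids = [i for i in ids if i not in scores.index]
    if missing_ids:
        raise ValueError(f"dogs missing from scores file: {missing_ids[:5]}")
    scores = scores.loc[ids]

    measure_names = []
    for name in scores.columns:
        norm = normalize_measure_name(name)
        if vocabulary is not None and norm not in {normalize_measure_name(v) for v in vocabulary}:
            raise ValueError(f"unknown cognitive measure {name!r}")
        measure_names.append(norm)
    if len(set(measure_names)) != len(measure_names):
        raise ValueError("duplicate measure columns after normalization")

    values = np.empty(scores.shape, dtype=float)
    for j, cname in enumerate(scores.columns):
        for i, cell in enumerate(scores[cname]):
            cell = cell.strip() if isinstance(cell, str) else cell
            if cell in missing_tokens:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric score {cell!r} for dog {scores.index[i]!r}, "
                        f"measure {cname!r}") from None

    matrix = CognitiveMeasureMatrix(ids, measure_names, values, ~np.isfinite(values))
    return records, matrix


def save_cohort(records: Sequence[DogRecord], matrix: CognitiveMeasureMatrix,
                roster_path, scores_path, delimiter: str = ",") -> None:
    """Write roster and scores CSVs in the dialect :func:`load_cohort` reads."""
    rows = [{
        "dog_id": r.dog_id, "sex": r.sex, "breed": r.breed,
        "age_years": repr(float(r.age_years)), "cohort": r.cohort,
        "status_flags": ";".join(sorted(r.status_flags)),
        "outcome": r.outcome or "", "aborted_tasks": r.aborted_tasks,
    } for r in records]
    pd.DataFrame(rows).to_csv(roster_path, sep=delimiter, index=False)

    with io.StringIO() as buf:
        buf.write(delimiter.join(["dog_id"] + list(matrix.measure_names)) + "\n")
        for i, dog in enumerate(matrix.dog_ids):
            cells = [dog]
            for j in range(matrix.n_measures):
                cells.append("" if matrix.missing_mask[i, j]
                             else repr(float(matrix.values[i, j])))
            buf.write(delimiter.join(cells) + "\n")
        text = buf.getvalue()
    with open(scores_path, "w", encoding="utf-8") as fh:
        fh.write(text)


def apply_exclusions(records: Sequence[DogRecord], matrix: CognitiveMeasureMatrix,
                     rules: Sequence[ExclusionRule]):
    """Apply exclusion rules in order; each dog is removed by the first rule it matches.

    Returns (surviving records, matching matrix subset, :class:`ExclusionReport`).
    """
    if [r.dog_id for r in records] != list(matrix.dog_ids):
        raise ValueError("records and matrix are not aligned")
    per_dog_missing = matrix.missing_mask.sum(axis=1)
    removed = {rule.name: 0 for rule in rules}
    keep = []
    for i, rec in enumerate(records):
        matched = None
        for rule in rules:
            if rule.kind == "status_flag" and rec.status_flags & rule.parameter:
                matched = rule
            elif rule.kind == "max_aborted_tasks" and rec.aborted_tasks > rule.parameter:
                matched = rule
            elif rule.kind == "max_missing_predictors" and per_dog_missing[i] > rule.parameter:
                matched = rule
            if matched:
                break
        if matched is None:
            keep.append(i)
        else:
            removed[matched.name] += 1
    report = ExclusionReport(initial_n=len(records), removed=removed, final_n=len(keep))
    return [records[i] for i in keep], matrix.subset_dogs(keep), report


def missingness_summary(matrix: CognitiveMeasureMatrix):
    """Missing-cell counts per dog and per measure (both sum to the total)."""
    per_dog = pd.Series(matrix.missing_mask.sum(axis=1), index=matrix.dog_ids,
                        name="n_missing")
    per_measure = pd.Series(matrix.missing_mask.sum(axis=0), index=matrix.measure_names,
                            name="n_missing")
    return per_dog, per_measure
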