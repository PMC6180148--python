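"""Workflow orchestration for the two experiment designs.

Experiment 1 (assistance dogs): preprocess the exploratory cohort (Box-Cox +
KNN imputation), screen measures, evaluate the eight-family ensemble under
repeated stratified CV, then freeze the fitted preprocessing and models and
apply them unchanged to an independent prediction cohort, reporting AUC,
accuracy, upper-quartile accuracy, and graduate-vs-release probability
t-tests.

Experiment 2 (detection dogs): discretize each performance measure, run the
cognition x performance association grid, aggregate directional consensus
scores, test them against zero, select a short battery, and hand the
hypothesized directions to the replication analysis (standardized-beta
panels with one-tailed one-sample tests).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort_data import CognitiveMeasureMatrix
from .consensus_screen import (AggregateScoreRow, build_aggregate_table,
                               consensus_null_test, select_short_battery,
                               test_association, ALPHA_DEFAULT)
from .ensemble_prediction import (FAMILIES, CVScheme, ModelConfig, PredictionSet,
                                  auc_roc, build_estimator, classify_threshold,
                                  group_probability_ttest, quartile_accuracy,
                                  raw_importance, repeated_cv, scale_importance,
                                  univariate_screen, _positive_proba)
from .performance_scoring import PerformanceTable
from .preprocess import (ImputeConfig, apply_transforms, discretize_quantiles,
                         fit_transforms, knn_impute)
from .replication_stats import beta_panel_test, standardized_beta

__all__ = ["RunManifest", "preprocess_cohort", "run_experiment1",
           "run_consensus", "run_replication", "run_experiment2"]


@dataclass
class RunManifest:
    """Provenance for one pipeline run: config, seed, inputs, outputs."""

    root_seed: int
    config: dict = field(default_factory=dict)
    package_version: str = __version__
    input_digests: Dict[str, str] = field(default_factory=dict)
    outputs: List[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def start(self) -> "RunManifest":
        self.started = time.strftime("%Y-%m-%dT%H:%M:%S")
        return self

    def finish(self) -> "RunManifest":
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        return self

    def add_input(self, path) -> None:
        with open(path, "rb") as fh:
            self.input_digests[str(path)] = hashlib.sha256(fh.read()).hexdigest()

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def preprocess_cohort(matrix: CognitiveMeasureMatrix,
                      transforms: Optional[dict] = None,
                      impute: Optional[ImputeConfig] = None):
    """Box-Cox transform then KNN-impute a cohort.

    Pass fitted ``transforms`` to re-apply a frozen preprocessing state (the
    exploratory-to-prediction workflow); otherwise they are fit here.
    Returns (completed matrix, transforms used).
    """
    if transforms is None:
        transforms = fit_transforms(matrix)
    transformed = apply_transforms(matrix, transforms)
    completed = knn_impute(transformed, impute or ImputeConfig())
    return completed, transforms


def _outcome_array(records_or_labels) -> np.ndarray:
    if hasattr(records_or_labels, "__len__") and len(records_or_labels) and \
            hasattr(records_or_labels[0], "outcome"):
        return np.array([1 if r.outcome == "graduate" else 0
                         for r in records_or_labels], dtype=int)
    return np.asarray(records_or_labels, dtype=int)


def run_experiment1(exploratory_matrix: CognitiveMeasureMatrix,
                    exploratory_outcomes,
                    prediction_matrix: Optional[CognitiveMeasureMatrix] = None,
                    prediction_outcomes=None,
                    families: Sequence[str] = FAMILIES,
                    scheme: Optional[CVScheme] = None,
                    threshold: float = 0.5,
                    seed: int = 0,
                    impute: Optional[ImputeConfig] = None,
                    freeze_preprocessing: bool = False) -> dict:
    """Fit and evaluate the classifier ensemble; optionally score a frozen
    prediction cohort.  Returns a nested report dict.

    Models are always frozen between cohorts.  Preprocessing (Box-Cox +
    imputation) is refit on the prediction cohort by default — a frozen
    power transform can be undefined on out-of-range new scores — and can
    be frozen instead with ``freeze_preprocessing``.
    """
    scheme = scheme or CVScheme(seed=seed)
    y = _outcome_array(exploratory_outcomes)
    completed, transforms = preprocess_cohort(exploratory_matrix, impute=impute)

    screen = univariate_screen(completed, y)
    report: dict = {
        "screen": [{"measure": r.measure, "sign": r.coefficient_sign,
                    "p_value": r.p_value, "rank": r.rank} for r in screen],
        "base_rate_exploratory": float(np.mean(y)),
        "cv": {}, "importance": None, "prediction": None,
    }

    X = completed.values
    raw_imp = {}
    fitted = {}
    for fam in families:
        config = ModelConfig(family=fam, threshold=threshold, seed=seed)
        cv = repeated_cv(completed, y, config, scheme)
        report["cv"][fam] = {**cv.summary, "resubstitution": cv.resubstitution}
        est = build_estimator(config)
        est.fit(X, y)
        fitted[fam] = est
        raw_imp[fam] = raw_importance(est, fam, X, y)
    imp = pd.DataFrame(raw_imp, index=completed.measure_names).T
    report["importance"] = scale_importance(imp)

    if prediction_matrix is not None:
        if list(prediction_matrix.measure_names) != list(completed.measure_names):
            missing = set(completed.measure_names) - set(prediction_matrix.measure_names)
            raise ValueError(f"prediction cohort missing measures: {sorted(missing)}")
        pred_completed, _ = preprocess_cohort(
            prediction_matrix,
            transforms=transforms if freeze_preprocessing else None,
            impute=impute)
        y_new = _outcome_array(prediction_outcomes)
        pred_report = {}
        for fam in families:
            p = _positive_proba(fitted[fam], pred_completed.values)
            ps = PredictionSet(list(pred_completed.dog_ids), p, y_new, threshold)
            entry = {
                "accuracy": float(np.mean(ps.predicted_label == y_new)),
                "auc": auc_roc(p, y_new),
            }
            try:
                q1, q4, _ = quartile_accuracy(ps)
                entry["q1_accuracy"], entry["q4_accuracy"] = q1, q4
            except ValueError:
                entry["q1_accuracy"] = entry["q4_accuracy"] = float("nan")
            for restrict, key in (("all", "ttest_all"), ("q1_and_q4", "ttest_q1q4")):
                try:
                    t, df, pval = group_probability_ttest(ps, restrict)
                    entry[key] = {"t": t, "df": df, "p": pval}
                except ValueError:
                    entry[key] = None
            pred_report[fam] = entry
        report["prediction"] = pred_report
        report["base_rate_prediction"] = float(np.mean(y_new))
    return report


def run_consensus(matrix: CognitiveMeasureMatrix, performance: PerformanceTable,
                  alpha: float = ALPHA_DEFAULT,
                  three_category_measures: Sequence[str] = (),
                  selection_threshold: int = 3,
                  manual_includes: Sequence[str] = ()) -> dict:
    """Exploratory consensus screen of cognition against performance measures.

    Performance measures named in ``three_category_measures`` are split into
    tertiles (ANOVA path); the rest into halves (t-test path).  Returns the
    association records, aggregate rows, consensus summary, battery
    selection, and the direction manifest for a later replication run.
    """
    perf = performance.data
    dogs = list(matrix.dog_ids)
    perf = perf.reindex(dogs)
    records = []
    for pm in perf.columns:
        n_cat = 3 if pm in three_category_measures else 2
        col = perf[pm].to_numpy(dtype=float)
        if np.unique(col[np.isfinite(col)]).size < n_cat:
            continue
        cats = discretize_quantiles(col, n_cat)
        for j, cm in enumerate(matrix.measure_names):
            x = np.where(matrix.missing_mask[:, j], np.nan, matrix.values[:, j])
            records.append(test_association(x, cats, cognitive_measure=cm,
                                            performance_measure=pm, alpha=alpha))
    rows = build_aggregate_table(records, alpha, measures=list(matrix.measure_names))
    summary = consensus_null_test(rows)
    selection = select_short_battery(rows, selection_threshold, manual_includes)
    directions = {m: ("positive" if r.aggregate >= 0 else "negative")
                  for m, _ in selection
                  for r in rows if r.cognitive_measure == m}
    return {"associations": records, "aggregate_rows": rows, "summary": summary,
            "selection": selection, "direction_manifest": directions}


def run_replication(matrix: CognitiveMeasureMatrix, performance: PerformanceTable,
                    direction_manifest: Mapping[str, str]) -> pd.DataFrame:
    """Replication panels: standardized betas of every performance outcome on
    each manifest predictor, with one-tailed one-sample tests per predictor."""
    if not direction_manifest:
        raise ValueError("replication requires a direction manifest from a "
                         "prior consensus run")
    perf = performance.data.reindex(matrix.dog_ids)
    rows = []
    for cm, direction in direction_manifest.items():
        if cm not in matrix.measure_names:
            raise ValueError(f"manifest predictor {cm!r} not in cognition matrix")
        j = matrix.measure_names.index(cm)
        x = np.where(matrix.missing_mask[:, j], np.nan, matrix.values[:, j])
        betas = []
        for pm in perf.columns:
            try:
                betas.append(standardized_beta(x, perf[pm].to_numpy(dtype=float),
                                               predictor=cm, outcome=pm).beta)
            except ValueError:
                continue
        res = beta_panel_test(betas, direction, predictor=cm)
        rows.append({"predictor": cm, "direction": direction,
                     "mean_beta": res.mean_beta, "sem_beta": res.sem_beta,
                     "t": res.t, "df": res.df, "p_one_tailed": res.p_one_tailed,
                     "n_outcomes": len(betas)})
    return pd.DataFrame(rows)


def run_experiment2(exploratory_matrix: CognitiveMeasureMatrix,
                    exploratory_performance: PerformanceTable,
                    replication_matrix: Optional[CognitiveMeasureMatrix] = None,
                    replication_performance: Optional[PerformanceTable] = None,
                    alpha: float = ALPHA_DEFAULT,
                    three_category_measures: Sequence[str] = (),
                    selection_threshold: int = 3,
                    manual_includes: Sequence[str] = ()) -> dict:
    """Full detection-dog workflow: consensus screen, then (optionally)
    replication on an independent cohort using the screen's directions."""
    consensus = run_consensus(exploratory_matrix, exploratory_performance,
                              alpha, three_category_measures,
                              selection_threshold, manual_includes)
    report = {"consensus": consensus, "replication": None}
    if replication_matrix is not None:
        if replication_performance is None:
            raise ValueError("replication cohort supplied without performance table")
        manifest = {m: d for m, d in consensus["direction_manifest"].items()
                    if m in replication_matrix.measure_names}
        report["replication"] = run_replication(replication_matrix,
                                                replication_performance, manifest)
    return report
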