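"""Graduation-outcome modelling: univariate screening, an eight-family classifier
ensemble under repeated stratified cross-validation, threshold classification,
quartile-stratified accuracy, 0-100 importance scaling, and the Welch t-tests
comparing predicted probabilities between graduates and releases.

The contract of this module is the resampling and evaluation machinery around
standard classifiers, not the classifiers' internals: model families are
realized by scikit-learn estimators (plus a compact in-package adaptive
regression splines classifier), all behind one fit/predict surface.

Orientation conventions, fixed and documented:
  * predicted probability is P(graduate); a probability >= threshold (default
    0.5, ties to graduate) classifies as graduate;
  * quartiles of predicted probability are the four near-equal strata of
    the probability ranking (stable sort, so probability ties are split by
    position); the 4th quartile is the highest-probability stratum;
  * the group t statistic is graduates minus releases (positive when
    graduates receive higher predicted probabilities), Welch variant,
    one-tailed for "graduates higher".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.base import BaseEstimator, ClassifierMixin

from ._mars import MARSClassifier
from .cohort_data import CognitiveMeasureMatrix

__all__ = [
    "FAMILIES", "ModelConfig", "CVScheme", "PredictionSet", "CrossValResult",
    "UnivariateScreenResult", "build_estimator", "univariate_screen",
    "repeated_cv", "classify_threshold", "auc_roc", "quartile_accuracy",
    "quartile_assignment", "scale_importance", "raw_importance",
    "group_probability_ttest",
]

FAMILIES = ("GLM", "LDA", "RR", "PLS", "NB", "MARS", "KNN", "RF")


@dataclass
class ModelConfig:
    """One model family plus its hyperparameters, threshold, and seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; "
                             f"expected one of {FAMILIES}")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be strictly between 0 and 1")


@dataclass
class CVScheme:
    """Repeated k-fold cross-validation layout (default 4 folds x 100 repeats)."""

    folds: int = 4
    repeats: int = 100
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class PredictionSet:
    """Per-dog predicted probabilities of graduation with true outcomes."""

    dog_ids: list
    probabilities: np.ndarray
    true_outcome: np.ndarray  # 1 = graduate, 0 = release
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.true_outcome = np.asarray(self.true_outcome, dtype=int)
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def predicted_label(self) -> np.ndarray:
        return classify_threshold(self.probabilities, self.threshold)


@dataclass
class CrossValResult:
    """Per-fold records and aggregates for one model family under repeated CV."""

    family: str
    records: pd.DataFrame  # repeat, fold, n_test, accuracy, auc, q1_accuracy, q4_accuracy
    summary: dict          # nan-aware means and SDs of the record columns
    resubstitution: dict   # accuracy/auc refitting on the full sample


@dataclass
class UnivariateScreenResult:
    measure: str
    coefficient_sign: int
    p_value: float
    rank: int
    degenerate: bool = False


class _PLSClassifier(BaseEstimator, ClassifierMixin):
    """Partial-least-squares discriminant scoring with clipped probabilities."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        ncomp = min(self.n_components, np.asarray(X).shape[1])
        self._pls = PLSRegression(n_components=ncomp)
        self._pls.fit(X, (y == self.classes_[-1]).astype(float))
        return self

    def predict_proba(self, X):
        p1 = np.clip(self._pls.predict(X).ravel(), 0.0, 1.0)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return np.where(self.predict_proba(X)[:, 1] >= 0.5,
                        self.classes_[-1], self.classes_[0])


def build_estimator(config: ModelConfig):
    """Instantiate the scikit-learn pipeline realizing one model family.

    All families see per-feature standardized inputs (the scale-sensitive
    families require it; it is harmless for the rest).  KNN defaults to
    7 neighbours; other hyperparameters default to the implementations'
    defaults and can be overridden through ``config.hyperparameters``.
    """
    hp = dict(config.hyperparameters)
    seed = config.seed % (2 ** 31)
    if config.family == "GLM":
        est = LogisticRegression(C=np.inf, max_iter=5000, **hp)
    elif config.family == "LDA":
        est = LinearDiscriminantAnalysis(**hp)
    elif config.family == "RR":
        est = LogisticRegression(C=hp.pop("C", 1.0), max_iter=5000, **hp)  # ridge
    elif config.family == "PLS":
        est = _PLSClassifier(n_components=hp.pop("n_components", 2))
    elif config.family == "NB":
        est = GaussianNB(**hp)
    elif config.family == "MARS":
        est = MARSClassifier(**hp)
    elif config.family == "KNN":
        est = KNeighborsClassifier(n_neighbors=hp.pop("neighbours", 7), **hp)
    elif config.family == "RF":
        est = RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 500), random_state=seed, **hp)
    else:  # pragma: no cover - guarded by ModelConfig
        raise ValueError(config.family)
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, CognitiveMeasureMatrix):
        if matrix.missing_mask.any():
            raise ValueError("matrix contains missing cells; impute before modelling")
        return matrix.values
    return np.asarray(matrix, dtype=float)


def _positive_proba(model, X, classes_positive=1) -> np.ndarray:
    proba = model.predict_proba(X)
    classes = model.classes_ if hasattr(model, "classes_") else model[-1].classes_
    idx = int(np.where(classes == classes_positive)[0][0])
    return proba[:, idx]


def univariate_screen(matrix: CognitiveMeasureMatrix, outcomes: Sequence[int]
                      ) -> List[UnivariateScreenResult]:
    """Single-predictor logistic regressions of outcome on each measure.

    Each measure is fit on its pairwise-complete dogs; the Wald p-value of
    the slope is recorded and results are returned sorted by ascending p.
    Measures constant overall or with <2 observations in either outcome
    class are skipped with a warning.  Complete separation is flagged
    (degenerate p of 0) rather than raised.
    """
    y_all = np.asarray(outcomes, dtype=int)
    results = []
    for j, name in enumerate(matrix.measure_names):
        x = matrix.values[:, j]
        obs = np.isfinite(x)
        xo, yo = x[obs], y_all[obs]
        if np.unique(xo).size < 2:
            warnings.warn(f"measure {name!r} is constant; skipped from screen")
            continue
        if min(np.sum(yo == 0), np.sum(yo == 1)) < 2:
            warnings.warn(f"measure {name!r} has <2 observations in an outcome "
                          "class; skipped from screen")
            continue
        X = sm.add_constant((xo - xo.mean()) / xo.std(ddof=1))
        degenerate = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(yo, X).fit(disp=0, maxiter=200)
            beta, p = fit.params[1], float(fit.pvalues[1])
            if not np.isfinite(p) or abs(beta) > 50:
                raise ValueError("separation")
        except Exception:
            warnings.warn(f"measure {name!r}: separation/degenerate fit; "
                          "p reported as 0")
            degenerate = True
            beta = np.sign(np.corrcoef(xo, yo)[0, 1])
            p = 0.0
        results.append(UnivariateScreenResult(
            measure=name, coefficient_sign=int(np.sign(beta)), p_value=p,
            rank=0, degenerate=degenerate))
    results.sort(key=lambda r: r.p_value)
    for rank, r in enumerate(results, start=1):
        r.rank = rank
    return results


def classify_threshold(probabilities: Sequence[float], threshold: float = 0.5
                       ) -> np.ndarray:
    """1 (graduate) where probability >= threshold, else 0; ties to graduate."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (p >= threshold).astype(int)


def auc_roc(probabilities: Sequence[float], labels: Sequence[int]) -> float:
    """ROC area = concordance probability, ties counted one-half."""
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("AUC undefined for single-class labels")
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))


def quartile_assignment(probabilities: Sequence[float]) -> np.ndarray:
    """Quartile (1..4) of each predicted probability.

    Dogs are ranked by predicted probability (stable sort, so equal
    probabilities are ordered by position) and the ranking is split into
    four near-equal strata; quartile 4 is always the highest-probability
    quarter.  The rank-based split guarantees the quartiles partition the
    set even under heavy probability ties.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.unique(p).size == 1:
        raise ValueError("quartiles undefined: all probabilities identical")
    n = len(p)
    ranks = np.empty(n, dtype=int)
    ranks[np.argsort(p, kind="stable")] = np.arange(n)
    return np.ceil(4 * (ranks + 1) / n).astype(int)


def quartile_accuracy(pred: PredictionSet) -> Tuple[float, float, np.ndarray]:
    """Accuracy within the lowest (1st) and highest (4th) probability quartiles."""
    if len(pred.probabilities) < 8:
        raise ValueError("need at least 8 predictions for quartile accuracy")
    q = quartile_assignment(pred.probabilities)
    labels = pred.predicted_label
    correct = labels == pred.true_outcome

    def acc(mask):
        return float(np.mean(correct[mask])) if mask.any() else np.nan

    return acc(q == 1), acc(q == 4), q


def repeated_cv(matrix, outcomes: Sequence[int], model: ModelConfig,
                scheme: Optional[CVScheme] = None,
                splits=None) -> CrossValResult:
    """Repeated k-fold cross-validation of one model family.

    Within each repeat, every dog is scored out-of-fold exactly once.  Each
    held-out fold contributes one record of accuracy, AUC, and 1st/4th-quartile
    accuracy (quartiles recomputed inside that fold's predictions; NaN where
    a fold is too small or its metrics are undefined).  Fully reproducible
    from the scheme and model seeds.

    ``splits`` optionally supplies the fold layout explicitly: a sequence of
    repeats, each a sequence of (train_indices, test_indices) pairs.  This
    bypasses the internal randomization (useful for auditing the harness
    against an external re-fit of known folds).
    """
    scheme = scheme or CVScheme()
    X = _as_array(matrix)
    y = np.asarray(outcomes, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("both outcome classes must be present")

    ss = np.random.SeedSequence(entropy=int(scheme.seed) % (2 ** 31),
                                spawn_key=(int(model.seed) % (2 ** 31),))
    n_repeats = scheme.repeats if splits is None else len(splits)
    repeat_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_repeats)]

    rows = []
    for rep, rep_seed in enumerate(repeat_seeds):
        if splits is not None:
            split = [(np.asarray(tr), np.asarray(te)) for tr, te in splits[rep]]
        else:
            for attempt in range(100):
                seed = (rep_seed + attempt) % (2 ** 31)
                splitter = (StratifiedKFold if scheme.stratified else KFold)(
                    n_splits=scheme.folds, shuffle=True, random_state=seed)
                split = list(splitter.split(X, y))
                if all(np.unique(y[tr]).size == 2 for tr, _ in split):
                    if attempt:
                        warnings.warn(f"repeat {rep}: single-class training fold; "
                                      "re-randomized")
                    break
            else:
                raise ValueError("could not draw folds with both classes in training")
        for fold_i, (tr, te) in enumerate(split):
            est = build_estimator(model)
            est.fit(X[tr], y[tr])
            p = _positive_proba(est, X[te])
            pred = PredictionSet(list(np.asarray(te)), p, y[te], model.threshold)
            acc = float(np.mean(pred.predicted_label == y[te]))
            try:
                auc = auc_roc(p, y[te])
            except ValueError:
                auc = np.nan
            try:
                q1, q4, _ = quartile_accuracy(pred)
            except ValueError:
                q1, q4 = np.nan, np.nan
            rows.append({"repeat": rep, "fold": fold_i, "n_test": len(te),
                         "accuracy": acc, "auc": auc,
                         "q1_accuracy": q1, "q4_accuracy": q4})

    records = pd.DataFrame(rows)
    metric_cols = ["accuracy", "auc", "q1_accuracy", "q4_accuracy"]
    summary = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for c in metric_cols:
            summary[f"mean_{c}"] = float(np.nanmean(records[c]))
            summary[f"sd_{c}"] = float(np.nanstd(records[c], ddof=1))

    est = build_estimator(model)
    est.fit(X, y)
    p_full = _positive_proba(est, X)
    resub = {
        "accuracy": float(np.mean(classify_threshold(p_full, model.threshold) == y)),
        "auc": auc_roc(p_full, y),
    }
    return CrossValResult(family=model.family, records=records,
                          summary=summary, resubstitution=resub)


def raw_importance(model_pipeline, family: str, X: np.ndarray, y: np.ndarray
                   ) -> np.ndarray:
    """Per-feature raw importance for one fitted family, before 0-100 scaling.

    Linear families use |standardized coefficient|; NB uses the standardized
    class-mean separation; KNN uses the model-free per-feature ROC distance
    from 0.5; MARS credits its hinge coefficients to their source features;
    RF uses impurity importances.  These follow each family's conventional
    importance notion; only the scaling and consensus are contract-tested.
    """
    est = model_pipeline[-1]
    if family in ("GLM", "RR", "LDA"):
        return np.abs(np.ravel(est.coef_))
    if family == "PLS":
        return np.abs(np.ravel(est._pls.coef_))
    if family == "NB":
        sd = np.sqrt(est.var_.mean(axis=0))
        return np.abs(est.theta_[1] - est.theta_[0]) / np.where(sd == 0, 1, sd)
    if family == "KNN":
        return np.array([abs(auc_roc(X[:, j], y) - 0.5) for j in range(X.shape[1])])
    if family == "MARS":
        return est.feature_deviance_credit(X.shape[1])
    if family == "RF":
        return est.feature_importances_
    raise ValueError(family)


def scale_importance(raw: pd.DataFrame) -> pd.DataFrame:
    """Scale each family's raw importances linearly to [0, 100] (min->0, max->100)."""
    out = raw.astype(float).copy()
    for fam in out.index:
        row = out.loc[fam]
        lo, hi = row.min(), row.max()
        if hi == lo:
            warnings.warn(f"family {fam!r}: all raw importances equal; scaled to 0")
            out.loc[fam] = 0.0
        else:
            out.loc[fam] = 100.0 * (row - lo) / (hi - lo)
    return out


def group_probability_ttest(pred: PredictionSet, restrict: str = "all"
                            ) -> Tuple[float, float, float]:
    """Welch t-test of predicted probability, graduates vs releases.

    Returns (t, Welch-Satterthwaite df, one-tailed p) for the alternative
    "graduates have higher predicted probability"; t is graduates minus
    releases.  ``restrict='q1_and_q4'`` keeps only dogs in the extreme
    probability quartiles (assignment shared with :func:`quartile_accuracy`).
    """
    if restrict not in ("all", "q1_and_q4"):
        raise ValueError("restrict must be 'all' or 'q1_and_q4'")
    p = pred.probabilities
    y = pred.true_outcome
    if restrict == "q1_and_q4":
        q = quartile_assignment(p)
        keep = (q == 1) | (q == 4)
        p, y = p[keep], y[keep]
    grad, rel = p[y == 1], p[y == 0]
    if len(grad) < 2 or len(rel) < 2:
        raise ValueError("need at least 2 dogs per outcome group")
    v1, v2 = grad.var(ddof=1) / len(grad), rel.var(ddof=1) / len(rel)
    if v1 + v2 == 0:
        return 0.0, float(len(grad) + len(rel) - 2), 0.5
    res = stats.ttest_ind(grad, rel, equal_var=False, alternative="greater")
    df = (v1 + v2) ** 2 / (v1 ** 2 / (len(grad) - 1) + v2 ** 2 / (len(rel) - 1))
    return float(res.statistic), float(df), float(res.pvalue)
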