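"""Predictor preprocessing: Box-Cox transforms, KNN imputation, z-scores, quantile bins.

These are the steps applied to cognitive scores before modelling (Box-Cox +
KNN imputation), before replication regressions (z-scoring), and before the
consensus screen (quantile discretization of performance measures).  Fitted
transform state is serializable so a preprocessing pipeline frozen on one
cohort can be re-applied unchanged to an independent cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import special, stats
from sklearn.impute import KNNImputer

from .cohort_data import CognitiveMeasureMatrix

__all__ = [
    "TransformRecord", "ImputeConfig",
    "boxcox_fit", "boxcox_apply", "fit_transforms", "apply_transforms",
    "knn_impute", "zscore", "discretize_quantiles",
]


@dataclass
class TransformRecord:
    """Fitted Box-Cox state for one measure: y -> ((y + shift)^lambda - 1)/lambda.

    ``passthrough`` marks measures (binary or near-constant) where a power
    transform is undefined or meaningless; apply is then the identity.
    """

    measure_name: str
    shift: float
    lam: float
    fitted_on_n: int
    passthrough: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TransformRecord":
        return cls(**d)


@dataclass
class ImputeConfig:
    """K-nearest-neighbour imputation settings.

    Distances are Euclidean over measures observed in both dogs, computed on
    per-measure standardized values; a missing cell is filled with the
    unweighted mean of the k nearest dogs' observed values for that measure.
    """

    k: int = 5
    distance: str = "euclidean_on_standardized"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.distance != "euclidean_on_standardized":
            raise ValueError(f"unsupported distance {self.distance!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def boxcox_fit(values: Sequence[float], measure_name: str = "") -> TransformRecord:
    """Fit a Box-Cox transform by profile maximum likelihood.

    Non-positive inputs are shifted by 1 - min before fitting so the power
    transform is defined; already-positive inputs are not shifted.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("need at least 3 finite values to fit Box-Cox")
    if np.all(x == x[0]):
        raise ValueError("Box-Cox transform undefined for constant input")
    shift = 0.0 if x.min() > 0 else 1.0 - x.min()
    _, lam = stats.boxcox(x + shift)
    return TransformRecord(measure_name=measure_name, shift=float(shift),
                           lam=float(lam), fitted_on_n=int(x.size))


def boxcox_apply(values: Sequence[float], record: TransformRecord) -> np.ndarray:
    """Apply a fitted Box-Cox transform; NaN (masked) entries pass through."""
    x = np.asarray(values, dtype=float)
    if record.passthrough:
        return x.copy()
    out = np.full(x.shape, np.nan)
    finite = np.isfinite(x)
    shifted = x[finite] + record.shift
    if np.any(shifted <= 0):
        bad = x[finite][shifted <= 0][0]
        raise ValueError(f"value {bad!r} is non-positive after shift {record.shift}")
    out[finite] = special.boxcox(shifted, record.lam)
    return out


def fit_transforms(matrix: CognitiveMeasureMatrix,
                   min_distinct: int = 3) -> Dict[str, TransformRecord]:
    """Fit one Box-Cox record per measure; binary/near-constant measures pass through."""
    records: Dict[str, TransformRecord] = {}
    for j, name in enumerate(matrix.measure_names):
        col = matrix.values[:, j]
        obs = col[np.isfinite(col)]
        if np.unique(obs).size < min_distinct:
            warnings.warn(f"measure {name!r} has <{min_distinct} distinct values; "
                          "Box-Cox skipped (passthrough)")
            records[name] = TransformRecord(name, 0.0, 1.0, int(obs.size), passthrough=True)
        else:
            records[name] = boxcox_fit(col, name)
    return records


def apply_transforms(matrix: CognitiveMeasureMatrix,
                     records: Dict[str, TransformRecord]) -> CognitiveMeasureMatrix:
    out = matrix.copy()
    for j, name in enumerate(out.measure_names):
        out.values[:, j] = boxcox_apply(out.values[:, j], records[name])
    return out


def knn_impute(matrix: CognitiveMeasureMatrix, config: Optional[ImputeConfig] = None
               ) -> CognitiveMeasureMatrix:
    """Complete a score matrix by K-nearest-neighbour imputation.

    Observed cells are never altered; the result is deterministic given the
    config.  A dog that shares no observed measure with any other dog cannot
    be placed in the neighbour space and is an error.
    """
    config = config or ImputeConfig()
    if config.k >= matrix.n_dogs:
        raise ValueError("k must be smaller than the number of dogs")
    X = matrix.values.copy()
    obs = ~matrix.missing_mask
    n_obs_per_measure = obs.sum(axis=0)
    short = [matrix.measure_names[j] for j in np.nonzero(n_obs_per_measure < config.k)[0]]
    if short:
        raise ValueError(f"measures observed on fewer than k dogs: {short}")
    if not np.any(matrix.missing_mask):
        return matrix.copy()

    # dogs with holes must overlap at least one other dog on some measure
    for i in np.nonzero(matrix.missing_mask.any(axis=1))[0]:
        overlap = (obs & obs[i]).any(axis=1)
        overlap[i] = False
        if not overlap.any():
            raise ValueError(f"dog {matrix.dog_ids[i]!r} shares no observed measure "
                             "with any other dog")

    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    imputer = KNNImputer(n_neighbors=config.k, weights="uniform")
    Z_full = imputer.fit_transform(Z)
    filled = Z_full * sd + mean
    filled[obs] = X[obs]  # bit-exact preservation of observed cells
    return CognitiveMeasureMatrix(list(matrix.dog_ids), list(matrix.measure_names),
                                  filled, np.zeros_like(matrix.missing_mask))


def zscore(values: Sequence[float]) -> np.ndarray:
    """Standardize to mean 0 and sample SD 1 (n-1 denominator); NaN preserved."""
    x = np.asarray(values, dtype=float)
    obs = x[np.isfinite(x)]
    if obs.size < 2:
        raise ValueError("need at least 2 finite values to z-score")
    sd = obs.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a zero-variance sequence")
    out = np.full(x.shape, np.nan)
    out[np.isfinite(x)] = (obs - obs.mean()) / sd
    return out


_LABELS = {2: ("below", "above"), 3: ("below", "average", "above")}


def discretize_quantiles(values: Sequence[float], n_categories: int = 2) -> np.ndarray:
    """Bin values into 2 (median split) or 3 (tertile) ordered categories.

    Boundaries are linear-interpolation sample percentiles (50th, or 33.3/66.7th);
    values exactly on a boundary go to the lower category.  NaN entries yield
    None labels.  Requires at least ``n_categories`` distinct finite values.
    """
    if n_categories not in _LABELS:
        raise ValueError("n_categories must be 2 or 3")
    x = np.asarray(values, dtype=float)
    obs = x[np.isfinite(x)]
    if np.unique(obs).size < n_categories:
        raise ValueError("fewer distinct values than requested categories")
    if n_categories == 2:
        cuts = [np.percentile(obs, 50)]
    else:
        cuts = [np.percentile(obs, 100 / 3), np.percentile(obs, 200 / 3)]
    labels = _LABELS[n_categories]
    out = np.empty(x.shape, dtype=object)
    for i, v in enumerate(x):
        if not np.isfinite(v):
            out[i] = None
        else:
            out[i] = labels[sum(v > c for c in cuts)]
    return out
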