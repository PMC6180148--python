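"""A compact degree-1 MARS-style classifier.

Forward pass: greedy least-squares selection of reflected hinge pairs
max(x - t, 0) / max(t - x, 0) over candidate knots at feature quantiles,
stopping at ``max_terms`` basis functions or when the residual sum of
squares stops improving.  The final model is a logistic regression on the
selected basis, which is the conventional way adaptive regression splines
are used for binary outcomes (least-squares basis search, GLM refit).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression


def _hinge_basis(X, terms):
    cols = [np.ones(X.shape[0])]
    for j, knot, sign in terms:
        d = sign * (X[:, j] - knot)
        cols.append(np.maximum(d, 0.0))
    return np.column_stack(cols)


class MARSClassifier(BaseEstimator, ClassifierMixin):
    """Adaptive piecewise-linear (hinge-basis) logistic classifier."""

    def __init__(self, max_terms: int = 8, knot_quantiles=(0.2, 0.35, 0.5, 0.65, 0.8)):
        self.max_terms = max_terms
        self.knot_quantiles = knot_quantiles

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        yy = (y == self.classes_[-1]).astype(float)

        candidates = []
        for j in range(X.shape[1]):
            for q in self.knot_quantiles:
                knot = float(np.quantile(X[:, j], q))
                candidates.append((j, knot))
        candidates = sorted(set(candidates))

        terms: list = []
        rss = np.sum((yy - yy.mean()) ** 2)
        while len(terms) < self.max_terms:
            best = None
            for j, knot in candidates:
                trial = terms + [(j, knot, +1), (j, knot, -1)]
                B = _hinge_basis(X, trial)
                coef, res, rank, _ = np.linalg.lstsq(B, yy, rcond=None)
                r = float(res[0]) if res.size else float(np.sum((yy - B @ coef) ** 2))
                if best is None or r < best[0]:
                    best = (r, j, knot)
            if best is None or best[0] >= rss - 1e-10:
                break
            rss, j, knot = best
            terms += [(j, knot, +1), (j, knot, -1)]
        self.terms_ = terms
        B = _hinge_basis(X, terms)[:, 1:]  # logistic adds its own intercept
        if B.shape[1] == 0:
            B = np.zeros((X.shape[0], 1))
        self._logit = LogisticRegression(max_iter=2000, C=1e3)
        self._logit.fit(B, yy)
        return self

    def _basis(self, X):
        B = _hinge_basis(np.asarray(X, dtype=float), self.terms_)[:, 1:]
        if B.shape[1] == 0:
            B = np.zeros((np.asarray(X).shape[0], 1))
        return B

    def predict_proba(self, X):
        p1 = self._logit.predict_proba(self._basis(X))[:, -1]
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return np.where(self.predict_proba(X)[:, 1] >= 0.5,
                        self.classes_[-1], self.classes_[0])

    def feature_deviance_credit(self, n_features: int) -> np.ndarray:
        """Sum of |logistic coefficients| of the hinge terms per input feature."""
        credit = np.zeros(n_features)
        coefs = np.abs(self._logit.coef_.ravel())
        for (j, _, _), c in zip(self.terms_, coefs):
            credit[j] += c
        return credit
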