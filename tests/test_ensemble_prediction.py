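"""Classifier-ensemble harness: thresholding, AUC, quartile accuracy,
repeated CV, importance scaling, screening, and group t-tests."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from dogcog.ensemble_prediction import (CVScheme, FAMILIES, ModelConfig,
                                        PredictionSet, auc_roc, build_estimator,
                                        classify_threshold,
                                        group_probability_ttest,
                                        quartile_accuracy, quartile_assignment,
                                        repeated_cv, scale_importance,
                                        univariate_screen)
from dogcog.synthetic_data import assistance_config, gen_cohort


def brute_force_auc(probs, labels):
    """Oracle: concordant-pair count over all label-discordant pairs, ties = 1/2."""
    probs, labels = np.asarray(probs), np.asarray(labels)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    total = concordant = 0.0
    for p in pos:
        for q in neg:
            total += 1
            concordant += 1.0 if p > q else (0.5 if p == q else 0.0)
    return concordant / total


class TestThresholdAndAuc:
    def test_threshold_rule_with_tie_to_graduate(self):
        labels = classify_threshold([0.2, 0.8, 0.5], 0.5)
        assert labels.tolist() == [0, 1, 1]

    def test_threshold_zero_predicts_all_graduate(self):
        assert classify_threshold([0.0, 0.3, 1.0], 0.0).tolist() == [1, 1, 1]

    def test_perfect_ordering_gives_auc_one(self):
        assert auc_roc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_equal_probabilities_give_half(self):
        assert auc_roc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_brute_force_pair_counting(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 20))
            probs = rng.random(n).round(1)  # rounding forces some ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auc_roc(probs, labels) == pytest.approx(
                brute_force_auc(probs, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_roc([0.1, 0.9], [1, 1])


class TestQuartiles:
    def test_probabilities_equal_to_outcomes_are_fully_accurate(self):
        ps = PredictionSet(list("abcdefgh"), [0, 0, 0, 0, 1, 1, 1, 1],
                           [0, 0, 0, 0, 1, 1, 1, 1])
        q1, q4, _ = quartile_accuracy(ps)
        assert q1 == 1.0 and q4 == 1.0

    def test_hand_built_eight_dog_case(self):
        probs = [0.05, 0.10, 0.30, 0.40, 0.60, 0.70, 0.90, 0.95]
        truth = [1, 0, 0, 1, 1, 0, 1, 0]
        ps = PredictionSet(list("abcdefgh"), probs, truth)
        q1, q4, q = quartile_accuracy(ps)
        # the sorted ranking splits into four strata of 2 dogs each
        assert q.tolist() == [1, 1, 2, 2, 3, 3, 4, 4]
        # q1 dogs predicted release (p<0.5): truth [1, 0] -> accuracy 0.5
        # q4 dogs predicted graduate: truth [1, 0] -> accuracy 0.5
        assert q1 == 0.5 and q4 == 0.5

    def test_overall_accuracy_is_weighted_mean_of_quartile_accuracies(self, rng):
        probs = rng.random(37)
        truth = rng.integers(0, 2, 37)
        ps = PredictionSet([str(i) for i in range(37)], probs, truth)
        _, _, q = quartile_accuracy(ps)
        correct = ps.predicted_label == truth
        weighted = sum(correct[q == k].sum() for k in (1, 2, 3, 4)) / len(truth)
        assert weighted == pytest.approx(correct.mean())

    def test_identical_probabilities_rejected(self):
        with pytest.raises(ValueError):
            quartile_assignment([0.5] * 10)


class TestRepeatedCV:
    def _toy(self, rng, n=12, k=3):
        X = rng.standard_normal((n, k))
        y = np.array([0, 1] * (n // 2))
        return X, y

    def test_toy_metrics_match_external_refit_of_same_folds(self, rng):
        """With explicit folds, harness metrics equal an independent re-fit
        done directly with scikit-learn, fold by fold."""
        X, y = self._toy(rng)
        idx = np.arange(12)
        folds = [(np.setdiff1d(idx, te), te)
                 for te in np.array_split(rng.permutation(idx), 4)]
        cv = repeated_cv(X, y, ModelConfig("GLM"), CVScheme(folds=4, repeats=1),
                         splits=[folds])
        for row, (tr, te) in zip(cv.records.itertuples(), folds):
            scaler = StandardScaler().fit(X[tr])
            clf = LogisticRegression(C=np.inf, max_iter=5000)
            clf.fit(scaler.transform(X[tr]), y[tr])
            p = clf.predict_proba(scaler.transform(X[te]))[:, 1]
            assert row.accuracy == pytest.approx(np.mean((p >= 0.5) == y[te]))
            if np.unique(y[te]).size == 2:
                assert row.auc == pytest.approx(brute_force_auc(p, y[te]))

    def test_out_of_fold_coverage_complete_per_repeat(self, rng):
        X, y = self._toy(rng, n=20)
        cv = repeated_cv(X, y, ModelConfig("GLM"), CVScheme(folds=4, repeats=3))
        per_repeat = cv.records.groupby("repeat")["n_test"].sum()
        assert (per_repeat == 20).all()
        assert len(cv.records) == 4 * 3

    def test_separable_data_scores_high(self, rng):
        n = 40
        y = np.array([0, 1] * (n // 2))
        X = np.column_stack([y + 0.01 * rng.standard_normal(n),
                             rng.standard_normal(n)])
        cv = repeated_cv(X, y, ModelConfig("GLM"), CVScheme(folds=4, repeats=2))
        assert cv.summary["mean_accuracy"] >= 0.95

    def test_identical_seeds_give_identical_results(self, rng):
        X, y = self._toy(rng, n=48)
        a = repeated_cv(X, y, ModelConfig("RF", {"n_estimators": 20}, seed=5),
                        CVScheme(folds=4, repeats=2, seed=9))
        b = repeated_cv(X, y, ModelConfig("RF", {"n_estimators": 20}, seed=5),
                        CVScheme(folds=4, repeats=2, seed=9))
        pd.testing.assert_frame_equal(a.records, b.records)
        assert a.summary == b.summary and a.resubstitution == b.resubstitution

    def test_single_class_outcomes_rejected(self, rng):
        X, _ = self._toy(rng)
        with pytest.raises(ValueError):
            repeated_cv(X, np.ones(12, dtype=int), ModelConfig("GLM"))

    @pytest.mark.parametrize("family", FAMILIES)
    def test_every_family_fits_and_scores(self, family, rng):
        X = rng.standard_normal((30, 4))
        y = (X[:, 0] + 0.5 * rng.standard_normal(30) > 0).astype(int)
        hp = {"n_estimators": 25} if family == "RF" else \
             {"neighbours": 5} if family == "KNN" else {}
        est = build_estimator(ModelConfig(family, hp, seed=1))
        est.fit(X, y)
        p = est.predict_proba(X)[:, -1]
        assert p.shape == (30,) and np.all((p >= 0) & (p <= 1))


class TestImportance:
    def test_linear_scaling_to_0_100(self):
        raw = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]}, index=["GLM"])
        out = scale_importance(raw)
        assert out.loc["GLM"].tolist() == [0.0, 50.0, 100.0]

    def test_already_scaled_row_unchanged(self):
        raw = pd.DataFrame({"a": [0.0], "b": [100.0]}, index=["GLM"])
        assert scale_importance(raw).loc["GLM"].tolist() == [0.0, 100.0]

    def test_invariant_to_positive_affine_transform(self, rng):
        vals = rng.random(6)
        raw = pd.DataFrame([vals], columns=list("abcdef"), index=["RF"])
        shifted = pd.DataFrame([vals * 3.5 + 2.0], columns=list("abcdef"),
                               index=["RF"])
        pd.testing.assert_frame_equal(scale_importance(raw),
                                      scale_importance(shifted))

    def test_constant_row_warns_and_zeroes(self):
        raw = pd.DataFrame({"a": [2.0], "b": [2.0]}, index=["NB"])
        with pytest.warns(UserWarning):
            out = scale_importance(raw)
        assert out.loc["NB"].tolist() == [0.0, 0.0]


class TestUnivariateScreen:
    def test_planted_predictor_ranks_first(self, matrix_factory, rng):
        n = 150
        signal = rng.standard_normal(n)
        y = (signal + 0.3 * rng.standard_normal(n) > 0).astype(int)
        X = np.column_stack([signal] + [rng.standard_normal(n) for _ in range(5)])
        results = univariate_screen(matrix_factory(X), y)
        assert results[0].measure == "m0" and results[0].rank == 1

    def test_constant_measure_skipped_with_warning(self, matrix_factory, rng):
        X = np.column_stack([np.ones(20), rng.standard_normal(20)])
        y = np.array([0, 1] * 10)
        with pytest.warns(UserWarning, match="constant"):
            results = univariate_screen(matrix_factory(X), y)
        assert [r.measure for r in results] == ["m1"]

    def test_ranks_are_a_permutation(self, matrix_factory, rng):
        X = rng.standard_normal((40, 6))
        y = rng.integers(0, 2, 40)
        y[:4] = [0, 0, 1, 1]
        results = univariate_screen(matrix_factory(X), y)
        assert sorted(r.rank for r in results) == list(range(1, len(results) + 1))


class TestGroupTtest:
    def test_identical_distributions_give_t0_p_half(self):
        probs = [0.2, 0.4, 0.6, 0.2, 0.4, 0.6]
        ps = PredictionSet(list("abcdef"), probs, [1, 1, 1, 0, 0, 0])
        t, df, p = group_probability_ttest(ps)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_matches_textbook_welch_formula(self):
        grad = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        rel = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        ps = PredictionSet([str(i) for i in range(10)],
                           np.concatenate([grad, rel]),
                           np.array([1] * 5 + [0] * 5))
        t, df, p = group_probability_ttest(ps)
        se = np.sqrt(grad.var(ddof=1) / 5 + rel.var(ddof=1) / 5)
        t_hand = (grad.mean() - rel.mean()) / se
        df_hand = (grad.var(ddof=1) / 5 + rel.var(ddof=1) / 5) ** 2 / (
            (grad.var(ddof=1) / 5) ** 2 / 4 + (rel.var(ddof=1) / 5) ** 2 / 4)
        assert t == pytest.approx(t_hand)        # -1.8974
        assert df == pytest.approx(df_hand)      # 5.882 (fractional df)
        assert p > 0.5                           # graduates NOT higher here

    def test_quartile_restriction_uses_shared_assignment(self, rng):
        probs = rng.random(24)
        truth = rng.integers(0, 2, 24)
        truth[:2] = [0, 1]
        ps = PredictionSet([str(i) for i in range(24)], probs, truth)
        q = quartile_assignment(probs)
        n_extreme = int(((q == 1) | (q == 4)).sum())
        assert n_extreme == 12  # two full quartiles of 24/4 dogs
        try:
            group_probability_ttest(ps, "q1_and_q4")
        except ValueError:
            pass  # legitimate when one outcome group is too small

    def test_tiny_group_rejected(self):
        ps = PredictionSet(list("abc"), [0.1, 0.5, 0.9], [1, 0, 0])
        with pytest.raises(ValueError):
            group_probability_ttest(ps)
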