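"""Association tests, aggregate consensus scores, null test, battery selection."""

import numpy as np
import pytest

from dogcog.consensus_screen import (AggregateScoreRow, AssociationRecord,
                                     build_aggregate_table, consensus_null_test,
                                     select_short_battery)
from dogcog.consensus_screen import test_association as association_test
from dogcog.datasets import detection_consensus_rows
from dogcog.pipeline import run_consensus
from dogcog.synthetic_data import (MeasureSpec, PerformanceSpec, detection_config,
                                   gen_cognitive_matrix, gen_performance_matrix,
                                   gen_quality)


class TestAssociation:
    def test_clear_positive_two_group_association(self, rng):
        cats = np.array(["below"] * 20 + ["above"] * 20, dtype=object)
        cog = np.concatenate([rng.normal(0, 1, 20), rng.normal(3, 1, 20)])
        rec = association_test(cog, cats)
        assert rec.test == "two_sample_t"
        assert rec.significant and rec.direction == "positive"

    def test_non_monotone_significant_anova_is_neutral(self, rng):
        cats = np.array(["below"] * 15 + ["average"] * 15 + ["above"] * 15,
                        dtype=object)
        cog = np.concatenate([rng.normal(1, 0.5, 15), rng.normal(5, 0.5, 15),
                              rng.normal(1, 0.5, 15)])
        rec = association_test(cog, cats)
        assert rec.test == "anova_3group"
        assert rec.significant and rec.direction == "neutral"

    def test_monotone_decreasing_anova_is_negative(self, rng):
        cats = np.array(["below"] * 15 + ["average"] * 15 + ["above"] * 15,
                        dtype=object)
        cog = np.concatenate([rng.normal(3, 0.5, 15), rng.normal(2, 0.5, 15),
                              rng.normal(1, 0.5, 15)])
        rec = association_test(cog, cats)
        assert rec.significant and rec.direction == "negative"

    def test_identical_distributions_not_significant(self):
        cats = np.array(["below"] * 5 + ["above"] * 5, dtype=object)
        cog = np.array([1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5])
        rec = association_test(cog, cats)
        assert not rec.significant

    def test_emptied_category_marks_unavailable(self):
        cats = np.array(["below"] * 5 + ["above"] * 5, dtype=object)
        cog = np.array([1.0, 2, 3, 4, 5] + [np.nan] * 5)
        rec = association_test(cog, cats)
        assert not rec.available and not rec.significant

    def test_orientation_flip_flips_direction(self, rng):
        cog = np.concatenate([rng.normal(0, 1, 20), rng.normal(2, 1, 20)])
        perf = np.concatenate([rng.normal(0, 1, 20), rng.normal(2, 1, 20)])
        from dogcog.preprocess import discretize_quantiles
        rec = association_test(cog, discretize_quantiles(perf, 2))
        flipped = association_test(cog, discretize_quantiles(-perf, 2))
        assert {rec.direction, flipped.direction} == {"positive", "negative"}


class TestAggregateTable:
    def test_row_arithmetic_enforced(self):
        with pytest.raises(ValueError):
            AggregateScoreRow("x", total=3, n_negative=1, n_neutral=0,
                              n_positive=1, aggregate=0)
        with pytest.raises(ValueError):
            AggregateScoreRow("x", total=2, n_negative=1, n_neutral=0,
                              n_positive=1, aggregate=1)

    def test_counts_from_published_screen_reproduce_aggregates(self):
        rows = {r.cognitive_measure: r.aggregate for r in detection_consensus_rows()}
        assert rows["odor discrimination"] == 5
        assert rows["transparent obstacle"] == -1  # mixed directions + a neutral
        assert rows["unsolvable task (manipulate container)"] == -6
        assert rows["cylinder"] == 0

    def test_only_significant_records_counted(self):
        recs = [
            AssociationRecord("m", "p1", "two_sample_t", 0.01, "positive", True),
            AssociationRecord("m", "p2", "two_sample_t", 0.20, "negative", False),
            AssociationRecord("m", "p3", "anova_3group", 0.01, "neutral", True),
        ]
        row, = build_aggregate_table(recs)
        assert (row.total, row.n_positive, row.n_negative, row.n_neutral,
                row.aggregate) == (2, 1, 0, 1, 1)

    def test_duplicate_pair_rejected(self):
        recs = [AssociationRecord("m", "p", "two_sample_t", 0.01, "positive", True)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            build_aggregate_table(recs)

    def test_measure_with_no_significant_hits_scores_zero(self):
        recs = [AssociationRecord("m", "p", "two_sample_t", 0.5, "positive", False)]
        row, = build_aggregate_table(recs)
        assert row.total == 0 and row.aggregate == 0


class TestConsensusNullTest:
    def test_published_aggregate_column_summary(self):
        s = consensus_null_test(detection_consensus_rows())
        assert s.df == 28
        assert round(s.t, 2) == 0.86
        assert round(s.p, 2) == 0.40
        assert round(s.mean_aggregate, 1) == 0.4
        assert round(s.sem_aggregate, 1) == 0.4
        assert round(s.mean_associations, 1) == 3.2
        assert round(s.sem_associations, 1) == 0.4

    def test_symmetric_aggregates_give_t_zero(self):
        rows = [AggregateScoreRow.from_counts(f"m{i}", abs(a), max(-a, 0), 0,
                                              max(a, 0))
                for i, a in enumerate([-2, -1, 0, 1, 2])]
        s = consensus_null_test(rows)
        assert s.t == pytest.approx(0.0)

    def test_zero_variance_rejected(self):
        rows = [AggregateScoreRow.from_counts(f"m{i}", 1, 0, 0, 1) for i in range(3)]
        with pytest.raises(ValueError):
            consensus_null_test(rows)


class TestBatterySelection:
    def test_published_rows_at_threshold_3(self):
        rows = detection_consensus_rows()
        selected = dict(select_short_battery(rows, 3))
        by_rule = {m for m, why in selected.items() if "aggregate" in why}
        assert by_rule == {"odor discrimination", "marker cue",
                          "causal reasoning (visual)", "arm pointing",
                          "memory - distraction", "working memory",
                          "unsolvable task (manipulate container)"}

    def test_threshold_above_max_selects_nothing(self):
        assert select_short_battery(detection_consensus_rows(), 7) == []

    def test_threshold_1_selects_all_nonzero(self):
        rows = detection_consensus_rows()
        nonzero = {r.cognitive_measure for r in rows if r.aggregate != 0}
        assert {m for m, _ in select_short_battery(rows, 1)} == nonzero

    def test_manual_include_flagged(self):
        rows = detection_consensus_rows()
        sel = dict(select_short_battery(rows, 3,
                                        ["laterality: object manipulation"]))
        assert sel["laterality: object manipulation"] == "manual include"

    def test_unknown_manual_include_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            select_short_battery(detection_consensus_rows(), 3, ["telepathy"])


def _independent_null_config(seed, n_measures=20, n_performance=8, n_dogs=120):
    cfg = detection_config(n_dogs=n_dogs, n_measures=n_measures,
                           n_performance=n_performance, seed=seed)
    for m in cfg.measure_spec:
        cfg.measure_spec[m] = MeasureSpec(loadings=(0.0, 0.0, 0.0), noise_sd=1.0)
    for p in cfg.performance_spec:
        cfg.performance_spec[p] = PerformanceSpec(loading=0.0, noise_sd=1.0)
    return cfg


class TestCalibrationAndRecovery:
    def test_null_aggregates_symmetric_about_zero(self):
        """With cognition independent of performance, positive and negative
        significant associations occur at near-equal rates."""
        pos = neg = 0
        for s in range(60):
            cfg = _independent_null_config(40_000 + s)
            q = gen_quality(cfg)
            matrix, _ = gen_cognitive_matrix(cfg, quality=q)
            perf = gen_performance_matrix(cfg, q)
            for r in run_consensus(matrix, perf)["aggregate_rows"]:
                pos += r.n_positive
                neg += r.n_negative
        total = pos + neg
        assert total > 100  # enough chance hits at alpha=0.05 to compare
        assert abs(pos - neg) / total < 0.15

    def test_planted_effects_recovered_with_signed_aggregates(self):
        hits_pos = hits_neg = 0
        n_rep = 40
        for s in range(n_rep):
            cfg = detection_config(
                n_dogs=150, n_measures=12, n_performance=8,
                planted_effects={"measure_00": 0.6, "measure_01": 0.6,
                                 "measure_02": -0.6},
                seed=50_000 + s)
            q = gen_quality(cfg)
            matrix, _ = gen_cognitive_matrix(cfg, quality=q)
            perf = gen_performance_matrix(cfg, q)
            agg = {r.cognitive_measure: r.aggregate
                   for r in run_consensus(matrix, perf)["aggregate_rows"]}
            hits_pos += agg["measure_00"] >= 3 and agg["measure_01"] >= 3
            hits_neg += agg["measure_02"] <= -3
        assert hits_pos / n_rep > 0.8
        assert hits_neg / n_rep > 0.8
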