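"""Ordered FPKM preprocessing, normalization and monotone-trend selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemsen.fpkm import (
    PipelineConfig,
    classify_trend,
    coefficient_of_variation,
    consensus_across_cultures,
    filter_failed,
    filter_low_expression,
    flag_housekeeping_anomaly,
    log2_evolution,
    normalize_baseline,
    normalize_housekeeping,
    run_pipeline,
)
from stemsen.synthdata import FpkmSimConfig, gen_fpkm_dataset

from conftest import make_matrix


class TestFilters:
    def test_fail_status_removed(self):
        m = make_matrix({f"F{i}": (2.0, 2.0, 2.0) for i in range(5)},
                        status={"F2": "fail"})
        kept, report = filter_failed(m)
        assert report.n_input == 5 and report.n_removed_fail == 1 and report.n_kept == 4
        assert "F2" not in kept.features

    def test_no_fail_is_identity(self):
        m = make_matrix({"A": (2.0, 2.0, 2.0), "B": (3.0, 3.0, 3.0)})
        kept, report = filter_failed(m)
        assert kept.features == ["A", "B"] and report.n_removed_fail == 0

    def test_all_fail_empty_result(self):
        m = make_matrix({"A": (2.0, 2.0, 2.0)}, status={"A": "fail"})
        kept, report = filter_failed(m)
        assert kept.features == [] and report.n_kept == 0

    def test_low_expression_boundary_rules(self):
        m = make_matrix({
            "LOW_INITIAL": (0.5, 3.0, 3.0),   # initial 0.5 < 1 -> removed
            "LOW_SUM": (1.0, 2.0, 1.9),       # sum 4.9 < 5 -> removed
            "BOUNDARY": (1.0, 2.0, 2.0),      # sum = 5, initial = 1 -> kept (strict rule)
        })
        kept, report = filter_low_expression(m)
        assert set(kept.features) == {"BOUNDARY"}
        assert set(report.removed_low) == {"LOW_INITIAL", "LOW_SUM"}

    def test_one_failing_culture_removes_feature_globally(self):
        m = make_matrix({"A": (2.0, 2.0, 2.0)}, cultures=("C0", "C1"))
        # degrade culture C1 below the sum threshold
        data = m.data.copy()
        data.loc[data["culture_id"] == "C1", ["t0", "t1", "t2"]] = [1.0, 1.0, 1.0]
        m = type(m)(data)
        kept, _ = filter_low_expression(m)
        assert kept.features == []

    def test_negative_threshold_rejected(self):
        m = make_matrix({"A": (2.0, 2.0, 2.0)})
        with pytest.raises(ValueError):
            filter_low_expression(m, sum_threshold=-1)

    def test_filter_order_irrelevant_without_overlap(self):
        # when no feature triggers both rules, the kept set is order-independent
        m = make_matrix(
            {"OK": (2.0, 2.0, 2.0), "BAD": (9.0, 9.0, 9.0), "DIM": (0.5, 1.0, 1.0)},
            status={"BAD": "fail"},
        )
        a, _ = filter_low_expression(filter_failed(m)[0])
        b, _ = filter_failed(filter_low_expression(m)[0])
        assert a.features == b.features == ["OK"]


class TestNormalization:
    def test_housekeeping_division(self):
        out = normalize_housekeeping([2.0, 4.0, 8.0], [1.0, 2.0, 4.0])
        assert out == pytest.approx([2.0, 2.0, 2.0])

    def test_self_normalization_is_ones(self):
        hk = [3.0, 5.0, 7.0]
        out = normalize_housekeeping(hk, hk)
        assert out == pytest.approx([1.0, 1.0, 1.0])
        assert coefficient_of_variation(out) == pytest.approx(0.0)

    def test_zero_housekeeping_names_timepoint(self):
        with pytest.raises(ValueError, match="t1"):
            normalize_housekeeping([1.0, 1.0, 1.0], [1.0, 0.0, 2.0])

    def test_baseline_starts_at_exactly_one(self):
        out = normalize_baseline([4.0, 2.0, 1.0])
        assert out[0] == 1.0
        assert out == pytest.approx([1.0, 0.5, 0.25])

    def test_zero_baseline_excluded(self):
        with pytest.raises(ValueError):
            normalize_baseline([0.0, 1.0, 2.0])

    def test_log2_evolution(self):
        assert log2_evolution([1.0, 2.0, 4.0]) == pytest.approx([0.0, 1.0, 2.0])
        assert log2_evolution([1.0, 1.0, 1.0]) == pytest.approx([0.0, 0.0, 0.0])
        assert log2_evolution([1.0, 0.5]) == pytest.approx([0.0, -1.0])
        with pytest.raises(ValueError):
            log2_evolution([1.0, 0.0])


class TestCoefficientOfVariation:
    def test_constant_series_zero(self):
        assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_sample_sd_over_mean(self):
        # SD with n-1 denominator of (1,2,3) is 1; mean is 2
        assert coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_zero_mean_undefined(self):
        assert math.isnan(coefficient_of_variation([1.0, -1.0]))

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale):
        base = np.array([1.0, 3.0, 2.0, 5.0])
        assert coefficient_of_variation(base * scale) == pytest.approx(
            coefficient_of_variation(base), rel=1e-9
        )


class TestAnomalyFlagging:
    def test_spike_flagged(self, toy_matrix):
        m = make_matrix({"GAPDH": (100.0, 110.0, 900.0)})
        flagged = flag_housekeeping_anomaly(m, "GAPDH", fold_limit=3.0)
        assert flagged["C0"] == [2]

    def test_constant_series_unflagged(self):
        m = make_matrix({"GAPDH": (100.0, 100.0, 100.0)})
        assert flag_housekeeping_anomaly(m, "GAPDH")["C0"] == []

    def test_infinite_limit_disables_flagging(self):
        m = make_matrix({"GAPDH": (100.0, 0.0, 900.0)})
        assert flag_housekeeping_anomaly(m, "GAPDH", fold_limit=math.inf)["C0"] == []

    def test_missing_housekeeping_raises(self):
        m = make_matrix({"A": (1.0, 1.0, 1.0)})
        with pytest.raises(KeyError):
            flag_housekeeping_anomaly(m, "GAPDH")


class TestTrendClassification:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ((0.0, 1.0, 2.0), "up"),
            ((0.0, -1.0, -2.0), "down"),
            ((0.0, 1.0, 0.5), "none"),
            ((0.0, 0.0, 0.0), "none"),
        ],
    )
    def test_examples(self, series, expected):
        assert classify_trend(series) == expected

    def test_min_step_gates_small_changes(self):
        assert classify_trend((0.0, 0.3, 0.6), min_step=0.5) == "none"
        assert classify_trend((0.0, 0.6, 1.2), min_step=0.5) == "up"

    def test_excluded_timepoints_dropped(self):
        # without exclusion the spike at t=2 breaks monotonicity
        assert classify_trend((0.0, 1.0, 0.2, 2.0)) == "none"
        assert classify_trend((0.0, 1.0, 0.2, 2.0), exclude=[2]) == "up"

    def test_too_few_points_is_none(self):
        assert classify_trend((0.0, 1.0, 2.0), exclude=[0, 1]) == "none"

    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_time_reversal_swaps_direction(self, series):
        forward = classify_trend(series)
        backward = classify_trend(series[::-1])
        swap = {"up": "down", "down": "up", "none": "none"}
        assert backward == swap[forward]


class TestConsensus:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            ({"a": "up", "b": "up", "c": "up", "d": "up"}, "up"),
            ({"a": "up", "b": "up", "c": "down", "d": "up"}, "none"),
            ({"a": "up", "b": "none", "c": "up", "d": "up"}, "none"),
            ({"a": "down", "b": "down"}, "down"),
        ],
    )
    def test_shared_direction(self, calls, expected):
        assert consensus_across_cultures(calls, list(calls)) == expected

    def test_missing_culture_raises(self):
        with pytest.raises(KeyError):
            consensus_across_cultures({"a": "up"}, ["a", "b"])


class TestPipeline:
    def test_noiseless_recovery_is_exact(self):
        cfg = FpkmSimConfig(n_features=300, n_cultures=4, noise_cv=0.0, seed=11)
        matrix, truth = gen_fpkm_dataset(cfg)
        result = run_pipeline(matrix, PipelineConfig())
        calls = dict(zip(result.trend_calls["feature_id"], result.trend_calls["consensus"]))
        for fid, planted in truth.directions.items():
            expected = "none" if planted == "flat" else planted
            assert calls[fid] == expected, fid

    def test_counts_conserve_features(self):
        cfg = FpkmSimConfig(n_features=100, noise_cv=0.1, seed=2,
                            baseline_fpkm_range=(0.5, 50.0))
        matrix, _ = gen_fpkm_dataset(cfg)
        result = run_pipeline(matrix, PipelineConfig())
        rep = result.report
        assert rep.n_input == rep.n_removed_fail + rep.n_removed_low + rep.n_kept
        assert rep.n_removed_low > 0  # low baselines guarantee some removals

    def test_empty_matrix_empty_outputs(self):
        m = make_matrix({"A": (2.0, 2.0, 2.0)}, status={"A": "fail"})
        result = run_pipeline(m, PipelineConfig())
        assert result.trend_calls.empty
        assert result.report.n_kept == 0

    def test_anomalous_housekeeping_timepoint_excluded_from_calls(self):
        # housekeeping spikes 9x at t2 in this culture: with flagging on, the
        # trend is called from t0..t1 only and the planted direction survives
        m = make_matrix({
            "GAPDH": (100.0, 100.0, 900.0),
            "UPG": (10.0, 20.0, 40.0),
        })
        with_flag = run_pipeline(m, PipelineConfig())
        calls = dict(zip(with_flag.trend_calls["feature_id"], with_flag.trend_calls["consensus"]))
        assert calls["UPG"] == "up"
        no_flag = run_pipeline(m, PipelineConfig(fold_limit=math.inf))
        calls = dict(zip(no_flag.trend_calls["feature_id"], no_flag.trend_calls["consensus"]))
        assert calls["UPG"] == "none"  # the spike distorts normalization at t2

    def test_scaling_raw_series_leaves_calls_unchanged(self):
        cfg = FpkmSimConfig(n_features=60, noise_cv=0.05, seed=8)
        matrix, _ = gen_fpkm_dataset(cfg)
        result1 = run_pipeline(matrix, PipelineConfig())
        scaled = matrix.data.copy()
        scaled[["t0", "t1", "t2"]] *= 10.0
        result2 = run_pipeline(type(matrix)(scaled), PipelineConfig())
        assert result1.trend_calls.equals(result2.trend_calls)
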