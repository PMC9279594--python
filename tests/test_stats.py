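"""Linear fits, slope comparison, FDR, ANOVA, t-test, multiple-range test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemsen.stats import (
    bh_fdr,
    compare_timeseries_ancova,
    fit_linear,
    multiple_range_bonferroni,
    one_way_anova,
    students_t,
)


class TestFitLinear:
    def test_exact_line(self):
        t = np.arange(5.0)
        fit = fit_linear(t, 2 * t + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-20)
        assert fit.goodness_of_fit == pytest.approx(1.0)

    def test_constant_response(self):
        fit = fit_linear([0.0, 1.0, 2.0], [4.0, 4.0, 4.0])
        assert fit.slope == pytest.approx(0.0)
        assert fit.goodness_of_fit == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        # independent oracle: solve X'X beta = X'y directly
        t = rng.uniform(0, 10, size=4)
        y = 0.7 * t - 2.0 + rng.normal(0, 1, size=4)
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        fit = fit_linear(t, y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-12)
        assert fit.slope == pytest.approx(beta[1], abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_linear([1.0], [2.0])
        with pytest.raises(ValueError):
            fit_linear([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAncova:
    def test_identical_noiseless_series(self):
        t = np.arange(6.0)
        y = 3 * t + 1
        res = compare_timeseries_ancova(t, y, t, y)
        assert res.delta_slope == pytest.approx(0.0)
        assert res.p_value == 1.0
        assert res.degenerate

    def test_symmetric_in_arguments(self, rng):
        t = np.arange(6.0)
        ya = 2 * t + rng.normal(0, 1, 6)
        yb = 2 * t + rng.normal(0, 1, 6)
        ab = compare_timeseries_ancova(t, ya, t, yb)
        ba = compare_timeseries_ancova(t, yb, t, ya)
        assert ab.p_value == pytest.approx(ba.p_value, rel=1e-12)
        assert ab.test_statistic == pytest.approx(-ba.test_statistic, rel=1e-12)

    def test_degrees_of_freedom(self, rng):
        t = np.arange(6.0)
        res = compare_timeseries_ancova(t, rng.normal(size=6), t, rng.normal(size=6))
        assert res.dof == 8

    def test_large_planted_difference_detected(self, rng):
        t = np.arange(6.0)
        sigma = 1.0
        sxx = np.sum((t - t.mean()) ** 2)
        se_diff = sigma * np.sqrt(2.0 / sxx)
        ya = 1.0 * t + rng.normal(0, sigma, 6)
        yb = (1.0 + 8 * se_diff) * t + rng.normal(0, sigma, 6)
        res = compare_timeseries_ancova(t, ya, t, yb)
        assert res.p_value < 0.001

    def test_degenerate_unequal_slopes(self):
        t = np.arange(6.0)
        res = compare_timeseries_ancova(t, 2 * t, t, 3 * t)
        assert res.p_value == 0.0 and res.degenerate

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            compare_timeseries_ancova([0, 1], [0, 1], [0, 1], [0, 2])


class TestBhFdr:
    def test_hand_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_monotone_dominating_and_envelope_stable(self, pvals):
        q = np.asarray(bh_fdr(pvals))
        order = np.argsort(pvals)
        q_sorted = q[order]
        assert np.all(np.diff(q_sorted) >= -1e-12)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        # BH output is a fixed point of the step-up monotonization
        remono = np.minimum.accumulate(q_sorted[::-1])[::-1]
        assert np.allclose(remono, q_sorted, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=15), st.randoms())
    @settings(max_examples=100, deadline=None)
    def test_permutation_equivariant(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        q = bh_fdr(pvals)
        q_perm = bh_fdr([pvals[i] for i in perm])
        assert q_perm == pytest.approx([q[i] for i in perm], abs=1e-12)


class TestOneWayAnova:
    def test_identical_groups(self):
        f, dof, p = one_way_anova([[1.0, 2.0, 3.0]] * 3)
        assert f == 0.0 and p == 1.0
        assert dof == (2, 6)

    def test_two_groups_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.5, 1, 6)
        f, _, p_f = one_way_anova([a, b])
        t, _, p_t = students_t(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_hand_computed_sums_of_squares(self):
        # brute-force oracle: explicit between/within mean squares
        groups = [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]]
        grand = np.mean(np.concatenate(groups))
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
        f_oracle = (ssb / 1) / (ssw / 4)
        f, dof, _ = one_way_anova(groups)
        assert f == pytest.approx(f_oracle, rel=1e-12)
        assert dof == (1, 4)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0], []])


class TestStudentsT:
    def test_equal_samples(self):
        t, dof, p = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and dof == 4

    def test_swap_negates_t_keeps_p(self, rng):
        a = rng.normal(0, 1, 5)
        b = rng.normal(1, 1, 7)
        t_ab, _, p_ab = students_t(a, b)
        t_ba, _, p_ba = students_t(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_pooled_variance_formula(self):
        # manual pooled-variance computation on a small instance
        a = np.array([10.0, 12.0, 14.0])
        b = np.array([9.0, 11.0])
        sp2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / 3
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 2))
        t, dof, _ = students_t(a, b)
        assert t == pytest.approx(t_oracle, rel=1e-12)
        assert dof == 3

    def test_zero_variance_unequal_means(self):
        t, _, p = students_t([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0 and np.isinf(t)

    @given(scale=st.floats(0.1, 10), shift=st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, scale, shift):
        a = np.array([1.0, 2.0, 4.0, 3.0])
        b = np.array([2.0, 5.0, 3.0])
        t0, _, p0 = students_t(a, b)
        t1, _, p1 = students_t(scale * a + shift, scale * b + shift)
        assert t1 == pytest.approx(t0, rel=1e-9)
        assert p1 == pytest.approx(p0, rel=1e-9)


class TestMultipleRange:
    def test_identical_groups_no_significance(self):
        res = multiple_range_bonferroni([[1.0, 2.0, 3.0]] * 3)
        assert len(res.comparisons) == 3
        assert not any(c.significant for c in res.comparisons)

    def test_adjusted_alpha(self):
        res = multiple_range_bonferroni([[1.0, 2.0], [1.5, 2.5], [1.2, 2.2]], alpha=0.05)
        assert res.adjusted_alpha == pytest.approx(0.05 / 3)

    def test_shifted_group_flagged(self, rng):
        base = [rng.normal(0, 1, 10) for _ in range(2)]
        shifted = rng.normal(10, 1, 10)  # 10 pooled SDs away
        res = multiple_range_bonferroni([*base, shifted])
        sig = {c.pair for c in res.comparisons if c.significant}
        assert sig == {(0, 2), (1, 2)}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            multiple_range_bonferroni([[1.0, 2.0], []])
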