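"""Robust and rank statistics: breakdown, efficiency, exactness, enumeration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cogpoint import (
    categorical_tests,
    lowess_fit,
    mann_whitney,
    mm_regression,
    spearman_rho,
    variance_ratio_test,
)


class TestMMRegression:
    def test_exact_linear_fit(self):
        x = np.arange(20.0)
        y = 3.0 + 2.0 * x
        fit = mm_regression(x, y)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(3.0, abs=1e-10)
        assert fit.scale == 0.0
        assert np.all(fit.weights == 1.0)

    def test_resists_leverage_outliers_where_ols_fails(self, rng):
        x = rng.normal(0, 1, 200)
        y = 1.0 * x + rng.normal(0, 1, 200)
        y_out = y.copy()
        y_out[np.argsort(x)[-60:]] += 20.0  # 30% gross outliers at +20 SD
        fit = mm_regression(x, y_out)
        ols_slope = np.polyfit(x, y_out, 1)[0]
        assert abs(fit.slope - 1.0) < 0.1
        assert abs(ols_slope - 1.0) > 0.5

    def test_efficiency_on_clean_gaussian(self, rng):
        x = rng.normal(0, 1, 500)
        y = 2.0 + 1.0 * x + rng.normal(0, 1, 500)
        fit = mm_regression(x, y)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
        se = np.sqrt(resid.var(ddof=2) / ((x - x.mean()) ** 2).sum())
        assert abs(fit.slope - slope) < 2 * se

    @pytest.mark.parametrize("frac", [0.10, 0.20, 0.30, 0.45])
    def test_breakdown_under_contamination(self, frac):
        # bounded leverage, arbitrary responses: slope stays near the clean fit
        rng = np.random.default_rng(int(frac * 100))
        x = rng.uniform(-3, 3, 400)
        y = 2.0 + 1.0 * x + rng.normal(0, 0.5, 400)
        clean_slope = mm_regression(x, y).slope
        k = int(frac * 400)
        y_out = y.copy()
        y_out[rng.choice(400, k, replace=False)] = 50.0
        fit = mm_regression(x, y_out)
        assert abs(fit.slope - clean_slope) < 0.5

    def test_weights_bounded_and_t_consistent(self, rng):
        x = rng.normal(0, 1, 100)
        y = x + rng.normal(0, 1, 100)
        fit = mm_regression(x, y)
        assert np.all((fit.weights >= 0) & (fit.weights <= 1))
        assert fit.t_slope == pytest.approx(fit.slope / fit.stderr_slope)
        assert fit.df == 98
        assert fit.converged

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mm_regression(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError):
            mm_regression([1.0, 2.0], [1.0, 2.0])


class TestLowess:
    def test_reproduces_line_exactly(self):
        x = np.linspace(0, 10, 40)
        y = 1.5 * x - 2.0
        assert np.abs(lowess_fit(x, y) - y).max() < 1e-8

    def test_span_one_no_robustifying_equals_line(self):
        x = np.linspace(0, 1, 30)
        y = 2.0 * x + 1.0
        fitted = lowess_fit(x, y, span=1.0, robust_iters=0)
        assert np.abs(fitted - y).max() < 1e-8

    def test_robustifying_damps_single_outlier(self):
        x = np.linspace(0, 10, 50)
        y = x.copy()
        y[25] += 10.0  # gross outlier on a line
        robust = lowess_fit(x, y, robust_iters=3)
        naive = lowess_fit(x, y, robust_iters=0)
        assert abs(robust[25] - x[25]) < 10.0 / 10
        assert abs(robust[25] - x[25]) < abs(naive[25] - x[25])

    def test_symmetric_quadratic_fit_is_symmetric(self):
        x = np.linspace(-1, 1, 41)
        y = x**2
        fitted = lowess_fit(x, y, span=1.0)
        assert np.allclose(fitted, fitted[::-1], atol=1e-10)

    def test_agrees_with_reference_implementation(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        x = np.sort(rng.uniform(0, 10, 80))
        y = np.sin(x) + rng.normal(0, 0.2, 80)
        ours = lowess_fit(x, y, span=0.5, robust_iters=2)
        ref = sm.nonparametric.lowess(y, x, frac=0.5, it=2, return_sorted=False)
        assert np.corrcoef(ours, ref)[0, 1] > 0.999
        assert np.abs(ours - ref).max() < 0.1 * np.ptp(y)

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError):
            lowess_fit(np.arange(100.0), np.arange(100.0), span=0.01)
        with pytest.raises(ValueError):
            lowess_fit(np.arange(4.0), np.arange(4.0))


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3, 5], [2, 4, 9, 11]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 5], [11, 9, 4, 2]) == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        # ranks (1,3,2,4) against (1,2,3,4): rho = 1 - 6*2/(4*15) = 0.8
        assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 10, 50).astype(float)
        y = x + rng.integers(0, 5, 50)
        assert spearman_rho(x, y) == pytest.approx(sps.spearmanr(x, y).statistic)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.integers(-100, 100), min_size=4, max_size=20, unique=True),
           st.integers(0, 3))
    def test_invariant_under_monotone_transforms(self, xs, which):
        rng = np.random.default_rng(0)
        x = np.array(xs, dtype=float)
        y = rng.permutation(len(x)).astype(float)
        if np.ptp(y) == 0:
            return
        transforms = [np.exp, lambda v: v**3, lambda v: 2 * v + 7,
                      lambda v: np.arctan(v / 50)]
        rho0 = spearman_rho(x, y)
        assert spearman_rho(transforms[which](x / 10), y) == pytest.approx(rho0)


def _wmw_exact_oracle(a, b):
    """Brute-force permutation distribution of U by pairwise counting."""
    pooled = np.concatenate([a, b])
    n, N = len(a), len(a) + len(b)

    def u_of(idx):
        sa = pooled[list(idx)]
        sb = pooled[[i for i in range(N) if i not in idx]]
        gt = sum(1.0 for x in sa for y in sb if x > y)
        eq = sum(1.0 for x in sa for y in sb if x == y)
        return gt + 0.5 * eq

    us = [u_of(idx) for idx in itertools.combinations(range(N), n)]
    u_obs = u_of(tuple(range(n)))
    us = np.array(us)
    p_lo = np.mean(us <= u_obs + 1e-9)
    p_hi = np.mean(us >= u_obs - 1e-9)
    return u_obs, min(1.0, 2 * min(p_lo, p_hi))


class TestMannWhitney:
    def test_extreme_separation(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        # one-sided tail is 1/6 over the 6 assignments; doubled for two sides
        assert res.p_value == pytest.approx(2 / 6)
        assert res.method == "exact"

    def test_identical_samples_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_exact_matches_enumeration_oracle(self, rng):
        for n, m in [(2, 3), (4, 4), (5, 6), (3, 8)]:
            a = rng.integers(0, 6, n).astype(float)
            b = rng.integers(0, 6, m).astype(float)
            u_ref, p_ref = _wmw_exact_oracle(a, b)
            res = mann_whitney(a, b)
            assert res.statistic == pytest.approx(u_ref)
            assert res.p_value == pytest.approx(p_ref)

    def test_approximation_close_to_resampling_reference(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.8, 1, 15)
        res = mann_whitney(a, b)
        assert res.method == "normal-approximation"
        # Monte-Carlo permutation reference for the two-sided p
        pooled = np.concatenate([a, b])
        obs = res.statistic
        mean_u = 15 * 15 / 2
        draws = np.empty(100_000)
        for i in range(len(draws)):
            rng.shuffle(pooled)
            ranks = sps.rankdata(pooled)
            draws[i] = ranks[:15].sum() - 15 * 16 / 2
        p_mc = np.mean(np.abs(draws - mean_u) >= abs(obs - mean_u) - 1e-9)
        assert abs(res.p_value - p_mc) < 0.02


class TestVarianceRatio:
    def test_identical_samples(self):
        res = variance_ratio_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_variance_scaling_law(self, rng):
        a = rng.normal(0, 2, 4000)
        b = rng.normal(0, 1, 4000)
        res = variance_ratio_test(a, b)
        assert res.statistic == pytest.approx(4.0, rel=0.1)
        assert res.df == (3999, 3999)

    def test_orientation_symmetry(self, rng):
        a = rng.normal(0, 3, 40)
        b = rng.normal(0, 1, 60)
        r1 = variance_ratio_test(a, b)
        r2 = variance_ratio_test(b, a)
        assert r1.statistic == r2.statistic
        assert r1.p_value == r2.p_value
        assert r1.df == r2.df

    def test_zero_denominator_flagged(self):
        res = variance_ratio_test([1.0, 2.0], [5.0, 5.0])
        assert math.isinf(res.statistic)
        assert res.flagged_infinite


def _fisher_oracle(table):
    """Two-sided Fisher p by direct factorial enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    total = r1 + r2

    def prob(k):
        return (
            math.factorial(r1) * math.factorial(r2) * math.factorial(c1)
            * math.factorial(total - c1)
            / (
                math.factorial(k) * math.factorial(r1 - k)
                * math.factorial(c1 - k) * math.factorial(r2 - c1 + k)
                * math.factorial(total)
            )
        )

    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(k) for k in range(k_min, k_max + 1)
               if prob(k) <= p_obs * (1 + 1e-7))


class TestCategoricalTests:
    def test_uniform_table(self):
        res = categorical_tests([[10, 10], [10, 10]])
        assert res.chi2 == pytest.approx(0.0)
        assert res.fisher_p == pytest.approx(1.0)

    def test_fisher_matches_enumeration(self):
        for table in ([[1, 9], [9, 1]], [[3, 7], [6, 2]], [[5, 0], [2, 8]]):
            res = categorical_tests(table)
            assert res.fisher_p == pytest.approx(_fisher_oracle(table))

    def test_row_swap_invariance(self):
        t = [[2, 8], [7, 3]]
        assert categorical_tests(t).fisher_p == pytest.approx(
            categorical_tests(t[::-1]).fisher_p
        )

    def test_chi2_matches_scipy(self):
        t = [[12, 5], [7, 20]]
        res = categorical_tests(t)
        ref = sps.chi2_contingency(t, correction=False)
        assert res.chi2 == pytest.approx(ref.statistic)
        assert res.chi2_p == pytest.approx(ref.pvalue)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            categorical_tests([[0, 0], [3, 4]])
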