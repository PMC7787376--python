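import math

import numpy as np
import pytest
from scipy import stats

from deathwords.inference import (
    PowerSpec,
    bonferroni_alpha,
    format_alpha,
    hier_regression,
    independent_t,
    paired_power,
    paired_t,
    pearson_r,
    required_n_paired,
)


class TestBonferroni:
    def test_three_comparisons_full_precision_and_display(self):
        a = bonferroni_alpha(0.05, 3)
        assert a == pytest.approx(0.05 / 3)
        assert format_alpha(a) == ".0166"
        # the display truncation must not feed back into comparisons
        assert a > 0.0166

    @pytest.mark.parametrize("alpha,k,expected", [(0.05, 1, 0.05), (0.05, 5, 0.01)])
    def test_simple_divisions(self, alpha, k, expected):
        assert bonferroni_alpha(alpha, k) == pytest.approx(expected)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestPairedT:
    def test_hand_worked_example_against_formula_oracle(self):
        x = np.array([5.0, 7.0, 6.0, 8.0])
        y = np.array([4.0, 6.0, 7.0, 5.0])
        res = paired_t(x, y)
        # independent oracle: direct formula evaluation
        d = x - y
        se = d.std(ddof=1) / math.sqrt(4)
        t_exp = d.mean() / se
        p_exp = 2 * stats.t.sf(abs(t_exp), 3)
        assert res.t == pytest.approx(t_exp, abs=1e-10)
        assert res.p == pytest.approx(p_exp, abs=1e-10)
        assert res.df == 3
        # cross-check against scipy's implementation
        sp = stats.ttest_rel(x, y)
        assert res.t == pytest.approx(sp.statistic, abs=1e-10)
        assert res.p == pytest.approx(sp.pvalue, abs=1e-10)

    def test_constant_shift_is_degenerate(self):
        res = paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        assert res.degenerate
        assert res.mean_diff == pytest.approx(1.0)
        assert np.isnan(res.cohen_d)

    def test_identical_vectors_degenerate_with_zero_diff(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.mean_diff == 0.0

    def test_incomplete_pairs_dropped(self):
        res = paired_t([1.0, np.nan, 3.0, 4.0], [0.5, 2.0, 1.0, np.nan])
        assert res.n_pairs == 2

    def test_dz_times_sqrt_n_equals_t_across_random_fixtures(self, rng):
        for _ in range(20):
            n = rng.integers(5, 60)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = paired_t(x, y)
            assert res.cohen_d * math.sqrt(res.n_pairs) == pytest.approx(res.t, abs=1e-9)
            assert res.mean_diff == pytest.approx(res.mean_a - res.mean_b, abs=1e-12)


class TestIndependentT:
    def test_identical_groups_t_zero(self):
        res = independent_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)

    def test_welch_equals_student_for_equal_variance_equal_n(self, rng):
        x = rng.normal(size=10)
        y = x + 0.3  # same sample variance by construction
        welch = independent_t(x, y, welch=True)
        student = independent_t(x, y, welch=False)
        assert welch.df == pytest.approx(student.df)
        assert welch.t == pytest.approx(student.t)

    def test_welch_df_at_most_pooled_df(self, rng):
        x = rng.normal(scale=3.0, size=8)
        y = rng.normal(scale=0.5, size=20)
        res = independent_t(x, y)
        assert res.df <= len(x) + len(y) - 2

    def test_hand_worked_4v4_against_oracles(self):
        x = np.array([3.1, 4.5, 2.8, 5.0])
        y = np.array([1.9, 2.2, 3.3, 2.6])
        res = independent_t(x, y, welch=True)
        sp = stats.ttest_ind(x, y, equal_var=False)
        assert res.t == pytest.approx(sp.statistic, abs=1e-10)
        assert res.p == pytest.approx(sp.pvalue, abs=1e-10)
        # pooled-SD Cohen's d, sign of (mean1 - mean2)
        sp2 = ((3 * x.var(ddof=1)) + 3 * y.var(ddof=1)) / 6
        assert res.cohen_d == pytest.approx((x.mean() - y.mean()) / math.sqrt(sp2))

    def test_double_degenerate_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            independent_t([1.0, 1.0], [2.0, 2.0])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(5.0)
        assert pearson_r(x, x).r == pytest.approx(1.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_hand_worked_example_against_scipy(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        res = pearson_r(x, y)
        sp = stats.pearsonr(x, y)
        assert res.r == pytest.approx(sp.statistic, abs=1e-12)
        assert res.p == pytest.approx(sp.pvalue, abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPower:
    def test_study_power_analysis_reproduced(self):
        # two-tailed paired test, d = .15, the reported alpha of .0166
        spec = required_n_paired(PowerSpec(d=0.15, alpha=0.0166, power=0.95))
        assert spec.n == 729
        assert spec.achieved_power >= 0.95
        assert paired_power(0.15, spec.n - 1, 0.0166) < 0.95  # minimality

    def test_monotonicity_in_d_power_alpha(self):
        base = required_n_paired(PowerSpec(d=0.3, alpha=0.05, power=0.8)).n
        assert required_n_paired(PowerSpec(d=0.5, alpha=0.05, power=0.8)).n <= base
        assert required_n_paired(PowerSpec(d=0.3, alpha=0.05, power=0.9)).n >= base
        assert required_n_paired(PowerSpec(d=0.3, alpha=0.01, power=0.8)).n >= base

    def test_normal_approximation_agreement_large_n(self):
        # for n >= 100 the noncentral-t answer agrees within 2 with the
        # corrected closed form ((z_{1-a/2}+z_{1-b})/d)^2 + z_{1-a/2}^2/2
        # (the plain z-formula underestimates by about z^2/2)
        for d, alpha, power in [(0.15, 0.05, 0.9), (0.1, 0.01, 0.8), (0.2, 0.05, 0.95)]:
            n_exact = required_n_paired(PowerSpec(d=d, alpha=alpha, power=power)).n
            za = stats.norm.ppf(1 - alpha / 2)
            z = za + stats.norm.ppf(power)
            n_approx = math.ceil((z / d) ** 2 + za**2 / 2)
            assert n_exact >= 100
            assert abs(n_exact - n_approx) <= 2

    def test_monte_carlo_power_oracle_moderate_effect(self, rng):
        # d=.8, alpha=.05, power=.8 -> simulate the paired test at the
        # returned n and compare the rejection rate
        spec = required_n_paired(PowerSpec(d=0.8, alpha=0.05, power=0.8))
        n, reps = spec.n, 20_000
        diffs = rng.normal(loc=0.8, scale=1.0, size=(reps, n))
        t = diffs.mean(axis=1) / (diffs.std(axis=1, ddof=1) / math.sqrt(n))
        crit = stats.t.ppf(1 - 0.05 / 2, n - 1)
        reject = np.mean(np.abs(t) > crit)
        assert reject == pytest.approx(spec.achieved_power, abs=0.01)

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(d=0.0, alpha=0.05, power=0.9)


class TestHierRegression:
    def make_table(self, rng, n=200):
        import pandas as pd

        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        x3 = rng.normal(size=n)
        y = 1.0 + 0.8 * x1 + 0.5 * x2 + rng.normal(scale=0.7, size=n)
        return pd.DataFrame({"y": y, "x1": x1, "x2": x2, "x3": x3})

    def test_outcome_as_predictor_gives_r2_one(self, rng):
        table = self.make_table(rng)
        table["ycopy"] = table["y"]
        res = hier_regression(table, "y", block1=["ycopy"], block2=["x1"])
        assert res.block1.r2 == pytest.approx(1.0)

    def test_orthogonal_design_delta_r2_is_sum_of_squared_correlations(self, rng):
        import pandas as pd

        n = 4096
        # orthonormal design via QR, standardized outcome contributions
        raw = rng.normal(size=(n, 3))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        X = q * math.sqrt(n - 1)  # columns: mean ~0, sd 1, mutually orthogonal
        beta = np.array([0.6, 0.3, 0.2])
        eps = rng.normal(size=n)
        eps -= X @ np.linalg.lstsq(X, eps, rcond=None)[0]  # make noise orthogonal too
        y = X @ beta + eps
        table = pd.DataFrame(X, columns=["x1", "x2", "x3"])
        table["y"] = y
        res = hier_regression(table, "y", block1=["x1"], block2=["x2", "x3"])
        r_y2 = np.corrcoef(y, X[:, 1])[0, 1]
        r_y3 = np.corrcoef(y, X[:, 2])[0, 1]
        assert res.delta_r2 == pytest.approx(r_y2**2 + r_y3**2, abs=1e-10)

    def test_within_block_permutation_invariance(self, rng):
        table = self.make_table(rng)
        a = hier_regression(table, "y", block1=["x1"], block2=["x2", "x3"])
        b = hier_regression(table, "y", block1=["x1"], block2=["x3", "x2"])
        assert a.block2.r2 == pytest.approx(b.block2.r2, abs=1e-12)
        assert a.delta_r2 == pytest.approx(b.delta_r2, abs=1e-12)

    def test_delta_r2_nonnegative_and_pvalues_valid(self, rng):
        for _ in range(5):
            table = self.make_table(rng, n=60)
            res = hier_regression(table, "y", block1=["x1"], block2=["x2", "x3"])
            assert res.delta_r2 >= 0
            assert 0 <= res.block2.p <= 1
            assert 0 <= res.delta_p <= 1

    def test_semipartial_is_signed_sqrt_of_unique_r2(self, rng):
        table = self.make_table(rng)
        res = hier_regression(table, "y", block1=["x1"], block2=["x2", "x3"])
        full = res.block2.r2
        reduced = hier_regression(table, "y", block1=["x1"], block2=["x3"]).block2.r2
        expected = math.copysign(
            math.sqrt(max(full - reduced, 0.0)),
            res.coefficients.loc["x2", "estimate"],
        )
        assert res.coefficients.loc["x2", "semipartial"] == pytest.approx(expected, abs=1e-10)

    def test_statsmodels_agreement_on_r2(self, rng):
        import statsmodels.api as sm

        table = self.make_table(rng)
        res = hier_regression(table, "y", block1=["x1"], block2=["x2", "x3"])
        X = sm.add_constant(table[["x1", "x2", "x3"]])
        assert res.block2.r2 == pytest.approx(sm.OLS(table["y"], X).fit().rsquared)

    def test_too_few_rows_rejected(self, rng):
        table = self.make_table(rng, n=5)
        with pytest.raises(ValueError, match="too few"):
            hier_regression(table, "y", block1=["x1"], block2=["x2", "x3"])
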