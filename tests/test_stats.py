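"""Group comparison tests against independent small-sample oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from swimmetrics.errors import DataError
from swimmetrics.stats import delta_ct, mann_whitney, t_test


def mw_exact_p_bruteforce(x, y, alternative="greater"):
    """Exact Mann-Whitney p by enumeration of all label assignments."""
    x = list(x)
    y = list(y)
    pooled = x + y
    n_x = len(x)

    def u_stat(xs, ys):
        return sum(1.0 if a > b else (0.5 if a == b else 0.0)
                   for a in xs for b in ys)

    u_obs = u_stat(x, y)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n_x):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(xs, ys)
        total += 1
        if alternative == "greater" and u >= u_obs:
            count += 1
        elif alternative == "less" and u <= u_obs:
            count += 1
    return count / total


class TestTTest:
    def test_paired_closed_form(self):
        # diffs [1, 2, 3]: mean 2, sd 1 -> t = 2 / (1/sqrt(3)) = 3.4641, df 2
        res = t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0], paired=True)
        assert res.statistic == pytest.approx(2 * math.sqrt(3), abs=1e-4)
        assert res.df == 2
        assert res.method == "paired t"

    def test_identical_paired_samples_degenerate(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert res.degenerate

    def test_two_sided_is_twice_min_one_sided(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.3, 1, 10)
        y = rng.normal(0, 1, 12)
        res_g = t_test(x, y, direction="greater")
        res_l = t_test(x, y, direction="less")
        assert res_g.p_two == pytest.approx(2 * min(res_g.p_one, res_l.p_one), rel=1e-9)

    def test_pooled_variance_matches_scipy_student(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 2, 6)
        res = t_test(x, y)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_two == pytest.approx(ref.pvalue)
        welch = t_test(x, y, welch=True)
        assert welch.method == "Welch t"
        assert welch.statistic != pytest.approx(res.statistic)

    def test_small_samples_rejected(self):
        with pytest.raises(DataError):
            t_test([1.0], [2.0, 3.0])

    def test_type_i_error_calibration(self):
        # 1000 seeded null simulations: rejection rate at alpha=0.05 must sit
        # inside the binomial 99.7% interval [0.05 +/- 3*sqrt(p q / 1000)]
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(1000):
            x = rng.normal(0, 1, 12)
            y = rng.normal(0, 1, 12)
            if t_test(x, y, direction="greater").p_one < 0.05:
                rejections += 1
        rate = rejections / 1000
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / 1000)


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        # x entirely below y: U_x = 0; one-sided p = 1 / C(6,3) = 0.05
        res = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], direction="less")
        assert res.statistic == 0.0
        assert res.p_one == pytest.approx(0.05)
        assert "exact" in res.method

    def test_identical_multisets(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(4.5)  # n_x n_y / 2
        assert res.p_two == pytest.approx(1.0)

    def test_exact_equals_enumeration_all_small_sizes(self):
        rng = np.random.default_rng(11)
        for n_x in range(1, 6):
            for n_y in range(1, 6):
                if n_x + n_y > 10:
                    continue
                vals = rng.permutation(np.arange(1.0, n_x + n_y + 1.0))
                x, y = vals[:n_x], vals[n_x:]
                for direction in ("greater", "less"):
                    res = mann_whitney(x, y, direction=direction)
                    assert res.p_one == pytest.approx(
                        mw_exact_p_bruteforce(x, y, direction), abs=1e-12
                    ), (n_x, n_y, direction)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 8)
        exact = mann_whitney(x, y, direction="less")
        assert "exact" in exact.method
        approx_p = sps.mannwhitneyu(x, y, alternative="less", method="asymptotic").pvalue
        assert abs(exact.p_one - approx_p) < 0.01

    def test_ties_fall_back_to_approximation(self):
        res = mann_whitney([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert "approx" in res.method


class TestDeltaCt:
    def test_worked_example(self):
        dct, expr = delta_ct(20.0, 15.0)
        assert dct == 5.0
        assert expr == pytest.approx(2.0**-5)

    def test_ddct_of_zero_is_fold_change_one(self):
        ddct, fold = delta_ct(20.0, 15.0, calibrator_dct=5.0)
        assert ddct == 0.0
        assert fold == 1.0

    def test_fold_change_halves_per_unit_ddct(self):
        _, f0 = delta_ct(20.0, 15.0, calibrator_dct=5.0)
        _, f1 = delta_ct(21.0, 15.0, calibrator_dct=5.0)
        assert f1 == pytest.approx(f0 / 2)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(DataError):
            delta_ct(float("nan"), 15.0)
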