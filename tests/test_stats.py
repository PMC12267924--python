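import itertools
import math

import numpy as np
import pytest

from paradoxflora.errors import InputError
from paradoxflora.stats import (bland_altman, classify_compensation,
                                ma_regression, paired_wilcoxon,
                                pct_threatened_histogram)


def perpendicular_sse_slope(x, y, tol=1e-10):
    """Independent oracle: minimize summed squared perpendicular distances
    over the line angle by dense grid + golden-section refinement."""
    x = np.asarray(x) - np.mean(x)
    y = np.asarray(y) - np.mean(y)

    def sse(theta):
        return float(np.sum((-math.sin(theta) * x + math.cos(theta) * y) ** 2))

    thetas = np.linspace(-math.pi / 2, math.pi / 2, 2001)
    k = int(np.argmin([sse(t) for t in thetas]))
    lo, hi = thetas[max(k - 1, 0)], thetas[min(k + 1, len(thetas) - 1)]
    invphi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    while b - a > tol:
        if sse(c) < sse(d):
            b, d = d, c
            c = b - invphi * (b - a)
        else:
            a, c = c, d
            d = a + invphi * (b - a)
    return math.tan((a + b) / 2)


def wilcoxon_enumeration_p(d):
    """Exact two-sided p by enumerating all sign assignments (no ties/zeros)."""
    d = np.asarray(d, float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    dist = [sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=len(d))]
    dist = np.array(dist)
    p = 2 * min((dist <= w_obs).mean(), (dist >= w_obs).mean())
    return min(1.0, p)


class TestMARegression:
    def test_identity_line(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        fit = ma_regression(x, x.copy())
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r == pytest.approx(1.0)

    def test_noiseless_steep_line(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        fit = ma_regression(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_perpendicular_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(10, 500))
        x = r.normal(0, 1 + r.random(), n)
        y = 0.35 * x + r.normal(0, 0.5, n)
        fit = ma_regression(x, y)
        assert fit.slope == pytest.approx(perpendicular_sse_slope(x, y), abs=1e-6)

    def test_axis_swap_inverts_slope(self, rng):
        x = rng.normal(0, 1, 200)
        y = 0.6 * x + rng.normal(0, 0.3, 200)
        f_xy = ma_regression(x, y)
        f_yx = ma_regression(y, x)
        assert f_yx.slope == pytest.approx(1.0 / f_xy.slope)

    def test_ma_differs_from_ols_under_noise(self, rng):
        x = rng.normal(0, 1, 300)
        y = 0.5 * x + rng.normal(0, 0.5, 300)
        ols = float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))
        fit = ma_regression(x, y)
        assert fit.slope != pytest.approx(ols, abs=1e-3)
        # on standardized data |MA| >= |OLS|
        xs = (x - x.mean()) / x.std()
        ys = (y - y.mean()) / y.std()
        assert abs(ma_regression(xs, ys).slope) >= abs(
            np.cov(xs, ys, ddof=1)[0, 1] / np.var(xs, ddof=1)) - 1e-12

    def test_ci_brackets_slope_and_orders(self, rng):
        x = rng.normal(0, 1, 150)
        y = x + rng.normal(0, 0.4, 150)
        fit = ma_regression(x, y)
        assert fit.slope_ci_low <= fit.slope <= fit.slope_ci_high

    def test_ci_coverage_in_calibrated_band(self):
        """Over 500 simulated datasets with a known major axis, the 95% CI
        covers the truth 93-97% of the time."""
        hits = 0
        b = 0.35
        for seed in range(500):
            r = np.random.default_rng(seed)
            t = r.normal(0, 1.0, 120)
            x = t + r.normal(0, 0.4, 120)
            y = b * t + r.normal(0, 0.4, 120)  # isotropic noise: MA axis = b
            fit = ma_regression(x, y)
            hits += fit.slope_ci_low <= b <= fit.slope_ci_high
        assert 465 <= hits <= 485

    def test_bootstrap_ci_close_to_analytic(self, rng):
        x = rng.normal(0, 1, 200)
        y = 0.35 * x + rng.normal(0, 0.3, 200)
        fa = ma_regression(x, y)
        fb = ma_regression(x, y, bootstrap=True, n_bootstrap=800, seed=0)
        assert fb.method == "bootstrap"
        assert fb.slope_ci_low == pytest.approx(fa.slope_ci_low, abs=0.08)
        assert fb.slope_ci_high == pytest.approx(fa.slope_ci_high, abs=0.08)

    def test_degenerate_and_small_inputs(self):
        with pytest.raises(InputError):
            ma_regression([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(InputError):
            # perfectly isotropic four-point cross: no major axis
            ma_regression([1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0])


class TestPairedWilcoxon:
    def test_all_zero_differences_error(self):
        a = np.arange(1.0, 9.0)
        with pytest.raises(InputError):
            paired_wilcoxon(a, a.copy())

    def test_pratt_gives_p_one_for_equal_vectors(self):
        a = np.arange(1.0, 9.0)
        res = paired_wilcoxon(a, a.copy(), zero_method="pratt")
        assert res.p_value == 1.0

    def test_constant_shift_detected(self, rng):
        b = rng.uniform(10, 100, 30)
        res = paired_wilcoxon(b + 10, b)
        assert res.p_value < 0.01
        assert res.median_a - res.median_b == pytest.approx(10.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_sign_enumeration(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 11))
        while True:  # tie-free differences so the exact null applies
            d = np.round(r.normal(0, 10, n), 3)
            if len(np.unique(np.abs(d))) == n and (d != 0).all():
                break
        res = paired_wilcoxon(d + 100.0, np.full(n, 100.0))
        assert res.p_value == pytest.approx(wilcoxon_enumeration_p(d), abs=1e-12)


class TestCompensation:
    def test_paper_scale_medians_are_net_increase(self):
        results, _, _ = classify_compensation(
            [type("P", (), {"accepted_name": "A sp", "aoo_naturalized": 60593.0,
                            "aoo_native_threatened": 37066.0})()])
        assert results[0].klass == "net_increase"

    def test_exact_tie_is_its_own_class(self):
        results, pct_p, pct_n = classify_compensation(
            [type("P", (), {"accepted_name": "A sp", "aoo_naturalized": 1000.0,
                            "aoo_native_threatened": 1000.0})()])
        assert results[0].klass == "tie"
        assert (pct_p, pct_n) == (0.0, 0.0)

    def test_constructed_forty_point_four(self):
        import pandas as pd

        n_partial, n_net = 693, 1023
        df = pd.DataFrame({
            "acceptedName": [f"S{i}" for i in range(n_partial + n_net)],
            "aooNaturalized": [10.0] * n_partial + [30.0] * n_net,
            "aooNativeThreatened": [20.0] * (n_partial + n_net),
        })
        _, pct_partial, pct_net = classify_compensation(df)
        assert round(pct_partial, 1) == 40.4
        assert round(pct_net, 1) == 59.6
        assert pct_partial + pct_net == pytest.approx(100.0)


class TestBlandAltman:
    def test_identical_vectors_collapse(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["mean_difference"] == 0.0
        assert res["limits"] == (0.0, 0.0)

    def test_constant_offset(self):
        res = bland_altman([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res["mean_difference"] == pytest.approx(1.0)
        assert res["sd"] == 0.0

    def test_limits_match_direct_recomputation(self, rng):
        a, b = rng.normal(4, 1, 50), rng.normal(4, 1, 50)
        res = bland_altman(a, b)
        d = a - b
        assert res["limits"][0] == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert res["limits"][1] == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))


class TestHistogram:
    def test_all_at_hundred_fill_top_bin(self):
        res = pct_threatened_histogram([100.0] * 7)
        assert res["mean"] == 100.0
        assert res["bin_counts"][-1] == 7
        assert sum(res["bin_counts"]) == 7

    def test_small_worked_example(self):
        res = pct_threatened_histogram([0.0, 10.0, 20.0])
        assert res["mean"] == pytest.approx(10.0)
        assert res["median"] == pytest.approx(10.0)
        assert res["bin_counts"][0] == 1   # [0, 5)
        assert res["bin_counts"][2] == 1   # [10, 15)
        assert res["bin_counts"][4] == 1   # [20, 25)

    def test_empty_is_input_error(self):
        with pytest.raises(InputError):
            pct_threatened_histogram([float("nan")])
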