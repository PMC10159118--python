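"""OLS fits against GC, significance codes, and the biased-COG call."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
import statsmodels.api as sm

from gcstruct.association import (
    RegressionError,
    call_cog_bias,
    fit_linear,
    signif_code,
)
from gcstruct.structure import SSComposition


def comp(h, e, c, n=100):
    return SSComposition(h, e, c, n, scope="protein")


class TestFitLinear:
    def test_exact_line(self):
        r = fit_linear([0.2, 0.4, 0.6], [1.4, 1.8, 2.2])
        assert r.slope == pytest.approx(2.0, abs=1e-12)
        assert r.intercept == pytest.approx(1.0, abs=1e-12)
        assert r.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_hand_ols(self):
        """Closed-form check: Sxy/Sxx slope, t-test p via the df=3 Student CDF."""
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 4, 5, 4, 5.0])
        r = fit_linear(x, y)
        sxx = float(np.sum((x - x.mean()) ** 2))  # 10
        sxy = float(np.sum((x - x.mean()) * (y - y.mean())))  # 6
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        assert r.slope == pytest.approx(slope, abs=1e-10)
        assert r.slope == pytest.approx(0.6, abs=1e-12)
        assert r.intercept == pytest.approx(2.2, abs=1e-12)
        rss = float(np.sum((y - (intercept + slope * x)) ** 2))
        se = math.sqrt(rss / (len(x) - 2) / sxx)
        t = slope / se
        # Student-t CDF with 3 df has the closed form
        # F(t) = 1/2 + (1/pi) * [ t / (sqrt(3) (1 + t^2/3)) + atan(t/sqrt(3)) ]
        cdf = 0.5 + (t / (math.sqrt(3) * (1 + t**2 / 3)) + math.atan(t / math.sqrt(3))) / math.pi
        assert r.p_value == pytest.approx(2 * (1 - cdf), abs=1e-10)

    def test_constant_response_flagged(self):
        r = fit_linear([0.1, 0.2, 0.3, 0.4], [2.0, 2.0, 2.0, 2.0])
        assert r.slope == 0.0 and r.p_value == 1.0 and r.zero_variance

    def test_degenerate_x(self):
        with pytest.raises(RegressionError):
            fit_linear([0.5, 0.5, 0.5], [1, 2, 3])

    def test_insufficient_n(self):
        with pytest.raises(RegressionError):
            fit_linear([0.1, 0.2], [1, 2])
        with pytest.raises(RegressionError):
            fit_linear([0.1, 0.2, 0.3], [1, 2, 3], degree=2)

    def test_degree1_matches_statsmodels(self, rng):
        x = rng.uniform(0.2, 0.7, size=25)
        y = 0.3 + 0.4 * x + rng.normal(0, 0.05, size=25)
        r = fit_linear(x, y)
        model = sm.OLS(y, sm.add_constant(x)).fit()
        assert r.slope == pytest.approx(model.params[1], rel=1e-10)
        assert r.p_value == pytest.approx(model.pvalues[1], rel=1e-8)
        assert r.r_squared == pytest.approx(model.rsquared, rel=1e-10)

    def test_degree2_recovers_quadratic(self):
        x = np.linspace(0.2, 0.7, 12)
        y = 1.0 - 0.5 * x + 3.0 * x**2
        r = fit_linear(x, y, degree=2)
        assert r.coefficients == pytest.approx((1.0, -0.5, 3.0), abs=1e-9)
        assert r.p_value < 1e-10  # exact quadratic: top coefficient certain

    def test_auto_degree_prefers_line_for_linear_data(self, rng):
        x = np.linspace(0.2, 0.7, 30)
        y = 0.1 + 0.2 * x + rng.normal(0, 0.01, size=30)
        assert fit_linear(x, y, degree="auto").degree == 1

    def test_auto_degree_detects_curvature(self):
        x = np.linspace(0.2, 0.7, 30)
        y = 0.1 + 0.2 * x + 5.0 * (x - 0.45) ** 2
        assert fit_linear(x, y, degree="auto").degree == 2

    @settings(max_examples=40, deadline=None)
    @given(
        a=st.floats(-5, 5), b=st.floats(-5, 5),
        seed=st.integers(0, 1000), n=st.integers(4, 30),
    )
    def test_exact_recovery_property(self, a, b, seed, n):
        x = np.random.Generator(np.random.PCG64(seed)).uniform(0, 1, size=n)
        if np.ptp(x) == 0:
            return
        r = fit_linear(x, a + b * x)
        assert r.slope == pytest.approx(b, abs=1e-8)
        assert r.intercept == pytest.approx(a, abs=1e-8)

    def test_slope_recovery_monte_carlo(self, rng):
        """Empirical SE of the slope matches the analytic SE within 10%."""
        n, sigma, b = 20, 0.3, 1.5
        x = rng.uniform(0, 1, size=n)
        analytic_se = sigma / math.sqrt(np.sum((x - x.mean()) ** 2))
        slopes = []
        for _ in range(1000):
            y = 0.5 + b * x + rng.normal(0, sigma, size=n)
            slopes.append(fit_linear(x, y).slope)
        assert np.mean(slopes) == pytest.approx(b, abs=4 * analytic_se / math.sqrt(1000) * 3)
        assert np.std(slopes) == pytest.approx(analytic_se, rel=0.10)


class TestSignifCode:
    @pytest.mark.parametrize(
        "p,code",
        [
            (0.0, "***"), (0.0005, "***"), (0.001, "***"),
            (0.0011, "**"), (0.01, "**"),
            (0.03, "*"), (0.05, "*"),
            (0.07, "."), (0.1, "."),
            (0.5, " "), (1.0, " "),
        ],
    )
    def test_coding_scheme(self, p, code):
        assert signif_code(p) == code

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            signif_code(1.5)
        with pytest.raises(ValueError):
            signif_code(-0.1)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_p(self, p1, p2):
        lo, hi = sorted((p1, p2))
        stars = {"***": 4, "**": 3, "*": 2, ".": 1, " ": 0}
        assert stars[signif_code(lo)] >= stars[signif_code(hi)]


class TestCallCOGBias:
    def _members(self, rng, n, coil_slope=0.0, noise=0.01):
        gc = rng.uniform(0.2, 0.75, size=n)
        out = []
        for g in gc:
            c = 0.3 + coil_slope * g + rng.normal(0, noise)
            h = 0.5 - coil_slope * g + rng.normal(0, noise)
            e = 1.0 - c - h
            out.append((float(g), comp(h, e, c)))
        return out

    def test_two_of_three_rule_via_constructed_data(self, rng):
        members = self._members(rng, 100, coil_slope=0.2, noise=0.01)
        call = call_cog_bias("COGX", members)
        assert call.biased
        assert call.coil.slope > 0
        assert call.coil.p_value < 0.001 and call.helix.p_value < 0.001

    def test_unbiased_when_independent(self, rng):
        members = self._members(rng, 50, coil_slope=0.0, noise=0.02)
        call = call_cog_bias("COGY", members)
        assert not call.biased

    def test_member_floor(self, rng):
        with pytest.raises(RegressionError):
            call_cog_bias("COGZ", self._members(rng, 5))

    def test_rule_counts_only_sub_alpha_fits(self, rng):
        # exactly one significant structure -> unbiased; sanity of the >=2 rule
        gc = np.linspace(0.2, 0.7, 40)
        members = []
        for g in gc:
            c = 0.3 + 0.3 * g + rng.normal(0, 0.005)  # strongly GC-coupled
            h = (1 - c) * 0.6 + rng.normal(0, 0.05)  # noisy, unrelated
            e = 1 - c - h
            members.append((float(g), comp(h, e, c)))
        call = call_cog_bias("COGW", members)
        sig = [f.p_value < 0.001 for f in call.fits.values()]
        assert call.biased == (sum(sig) >= 2)
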