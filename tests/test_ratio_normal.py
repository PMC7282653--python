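"""The Cauchy-like ratio-of-normals distribution: CDF, quantile, sampler."""

import math

import numpy as np
import pytest

from niretain import (
    InvalidParameterError,
    NullBoundaryParams,
    RatioNormalParams,
    cauchy_like_cdf,
    cauchy_like_pdf,
    cauchy_like_quantile,
    ratio_normal_cdf,
    sample_cauchy_like,
)
from conftest import SEED


def mc_ratio_cdf(t, a, b, n, seed):
    """Independent brute-force oracle: empirical P((a+X)/(b+Y) <= t)."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    with np.errstate(divide="ignore"):
        w = (a + x) / (b + y)
    p = float(np.mean(w <= t))
    se = math.sqrt(max(p * (1 - p), 1e-12) / n)
    return p, se


class TestRatioNormalCdf:
    def test_standard_cauchy_closed_form(self):
        # a = b = 0 reduces to the standard Cauchy
        assert ratio_normal_cdf(0.0, 0.0, 0.0) == pytest.approx(0.5, abs=1e-8)
        assert ratio_normal_cdf(1.0, 0.0, 0.0) == pytest.approx(0.75, abs=1e-8)
        for t in np.linspace(-5, 5, 21):
            closed = 0.5 + math.atan(t) / math.pi
            assert ratio_normal_cdf(float(t), 0.0, 0.0) == pytest.approx(closed, abs=1e-8)

    def test_limits_and_range(self):
        assert ratio_normal_cdf(math.inf, 1.0, 2.0) == 1.0
        assert ratio_normal_cdf(-math.inf, 1.0, 2.0) == 0.0
        grid = np.linspace(-40, 40, 161)
        vals = [ratio_normal_cdf(float(t), -1.5, 2.5) for t in grid]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert all(v2 >= v1 - 1e-12 for v1, v2 in zip(vals, vals[1:]))

    def test_against_sampling_oracle_xeloda_point(self):
        # parameters of the pooled Xeloda analysis (8-trial meta-analysis)
        t, a, b = 0.17848, -1.9560, 4.0438
        p_mc, se = mc_ratio_cdf(t, a, b, n=10**7, seed=SEED)
        assert ratio_normal_cdf(t, a, b) == pytest.approx(p_mc, abs=3 * se)

    def test_oracle_agreement_at_random_parameter_points(self, rng):
        # integrated CDF vs brute-force sampling over a spread of (t, a, b)
        for i in range(20):
            a = float(rng.uniform(-3, 3))
            b = float(rng.uniform(-4, 4))
            t = float(rng.uniform(-2, 2))
            p_mc, se = mc_ratio_cdf(t, a, b, n=2 * 10**5, seed=SEED + 100 + i)
            assert ratio_normal_cdf(t, a, b) == pytest.approx(
                p_mc, abs=max(3 * se, 1e-4)
            ), f"mismatch at t={t}, a={a}, b={b}"

    def test_normal_limit_large_b(self):
        # as b grows with a/b = c fixed, (a+X)/(b+Y) -> N(c, (1+c^2)/b^2);
        # the residual skew term decays like 1/b
        from scipy.special import ndtr

        c = 0.5
        for b, tol in ((50.0, 5e-3), (200.0, 1e-3)):
            sd = math.sqrt(1 + c * c) / b
            for k in (-2.0, -0.5, 0.0, 1.0, 2.0):
                t = c + k * sd
                assert ratio_normal_cdf(t, c * b, b) == pytest.approx(
                    float(ndtr(k)), abs=tol
                )

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            ratio_normal_cdf(0.0, math.nan, 1.0)
        with pytest.raises(InvalidParameterError):
            ratio_normal_cdf(0.0, 0.0, math.inf)
        with pytest.raises(InvalidParameterError):
            ratio_normal_cdf(math.nan, 0.0, 1.0)


class TestParams:
    def test_ratio_params_validation(self):
        with pytest.raises(InvalidParameterError):
            RatioNormalParams(a=0.0, b=1.0, r=0.0)
        with pytest.raises(InvalidParameterError):
            RatioNormalParams(a=math.inf, b=1.0, r=1.0)

    def test_null_boundary_pins_numerator_offset(self):
        p = NullBoundaryParams(b=3.0, r=1.5, delta0=0.5)
        assert p.a == pytest.approx(-(1 - 0.5) * 3.0 / 1.5)
        with pytest.raises(InvalidParameterError):
            NullBoundaryParams(b=3.0, r=-1.0, delta0=0.5)


class TestCauchyLikeCdf:
    def test_upper_limit(self):
        p = NullBoundaryParams(b=3.1213, r=1.1573, delta0=0.5)
        assert cauchy_like_cdf(math.inf, p) == 1.0
        assert cauchy_like_cdf(-math.inf, p) == 0.0

    def test_published_upper_tail(self):
        # upper tail at the observed retention fraction of study S014695
        p = NullBoundaryParams(b=3.1213, r=1.1573, delta0=0.5)
        assert 1 - cauchy_like_cdf(1.0154, p) == pytest.approx(0.0830, abs=2e-4)

    def test_matches_direct_simulation(self):
        params = NullBoundaryParams(b=2.0, r=1.0, delta0=0.5)
        rng = np.random.default_rng(SEED)
        n = 10**7
        z = params.r * (params.a + rng.standard_normal(n)) / (
            params.b + rng.standard_normal(n)
        ) + 1.0
        p_mc = float(np.mean(z <= 0.8))
        se = math.sqrt(p_mc * (1 - p_mc) / n)
        assert cauchy_like_cdf(0.8, params) == pytest.approx(p_mc, abs=3 * se)

    def test_pdf_integrates_to_cdf_increment(self):
        from scipy.integrate import quad

        params = NullBoundaryParams(b=3.0, r=1.2, delta0=0.5)
        mass, _ = quad(lambda z: cauchy_like_pdf(z, params), 0.0, 2.0, limit=200)
        assert mass == pytest.approx(
            cauchy_like_cdf(2.0, params) - cauchy_like_cdf(0.0, params), abs=1e-6
        )


class TestQuantile:
    def test_round_trip(self):
        params = NullBoundaryParams(b=3.0, r=1.0, delta0=0.5)
        for z in (0.0, 0.5, 1.0, 1.5):
            p = cauchy_like_cdf(z, params)
            assert cauchy_like_quantile(p, params) == pytest.approx(z, abs=1e-6)

    def test_monotone(self):
        params = NullBoundaryParams(b=2.0, r=0.7, delta0=0.7)
        qs = [cauchy_like_quantile(p, params) for p in (0.1, 0.5, 0.9, 0.99)]
        assert qs == sorted(qs)
        assert cauchy_like_quantile(0.9, params) < cauchy_like_quantile(0.99, params)

    def test_against_empirical_percentile(self):
        params = NullBoundaryParams(b=4.0, r=0.5, delta0=0.5)
        q = cauchy_like_quantile(0.975, params)
        draws = sample_cauchy_like(10**6, params, seed=SEED)
        frac_below = float(np.mean(draws <= q))
        se = math.sqrt(0.975 * 0.025 / draws.size)
        assert frac_below == pytest.approx(0.975, abs=3 * se)

    def test_domain_error(self):
        params = NullBoundaryParams(b=3.0, r=1.0, delta0=0.5)
        for p in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(InvalidParameterError):
                cauchy_like_quantile(p, params)


class TestSampler:
    def test_deterministic_under_seed(self):
        params = NullBoundaryParams(b=2.0, r=1.3, delta0=0.5)
        a = sample_cauchy_like(1000, params, seed=SEED)
        b = sample_cauchy_like(1000, params, seed=SEED)
        np.testing.assert_array_equal(a, b)

    def test_empirical_cdf_matches_integrated(self):
        params = NullBoundaryParams(b=2.5, r=1.0, delta0=0.7)
        draws = sample_cauchy_like(10**6, params, seed=SEED)
        p_emp = float(np.mean(draws <= 1.0))
        se = math.sqrt(p_emp * (1 - p_emp) / draws.size)
        assert cauchy_like_cdf(1.0, params) == pytest.approx(p_emp, abs=3 * se)

    def test_rejects_nonpositive_n(self):
        params = NullBoundaryParams(b=2.0, r=1.0, delta0=0.5)
        with pytest.raises(InvalidParameterError):
            sample_cauchy_like(0, params, seed=1)
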