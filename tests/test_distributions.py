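"""Closed-form skew-Laplace math against quadrature and sampling oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from skewlap import (
    GammaModelParams,
    SkewLaplaceParams,
    gamma_model_pdf,
    sl_cdf,
    sl_entropy,
    sl_loglinear,
    sl_moments,
    sl_pdf,
    sl_quantile,
    sl_sample,
)
from conftest import quad_split

# moderate, well-conditioned parameter ranges for property tests
params_st = st.builds(
    SkewLaplaceParams,
    mu=st.floats(-100.0, 100.0),
    alpha=st.floats(0.01, 50.0),
    beta=st.floats(0.01, 50.0),
)


class TestPdf:
    def test_mode_value_is_peak(self):
        assert sl_pdf(0.0, SkewLaplaceParams(0, 1, 1)) == pytest.approx(0.5)

    def test_direct_substitution_one_unit_right(self):
        assert sl_pdf(1.0, SkewLaplaceParams(0, 1, 1)) == pytest.approx(0.5 * np.exp(-1), rel=1e-12)

    def test_positive_and_continuous_at_mode(self):
        p = SkewLaplaceParams(2.0, 0.3, 1.7)
        eps = 1e-12
        assert sl_pdf(p.mu - eps, p) == pytest.approx(sl_pdf(p.mu + eps, p), rel=1e-9)
        assert np.all(np.asarray(sl_pdf(np.linspace(-50, 50, 101), p)) > 0)

    def test_integrates_to_one_quadrature(self):
        p = SkewLaplaceParams(2.0, 0.3, 1.7)
        assert quad_split(lambda x: sl_pdf(x, p), p) == pytest.approx(1.0, abs=1e-8)

    def test_nonfinite_x_rejected(self):
        with pytest.raises(ValueError):
            sl_pdf(np.nan, SkewLaplaceParams(0, 1, 1))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(params_st)
    def test_normalization_property(self, p):
        assert quad_split(lambda x: sl_pdf(x, p), p) == pytest.approx(1.0, abs=1e-8)


class TestCdf:
    def test_symmetric_median_at_mode(self):
        assert sl_cdf(0.0, SkewLaplaceParams(0, 1, 1)) == pytest.approx(0.5)

    def test_mode_probability_is_beta_fraction(self):
        assert sl_cdf(0.0, SkewLaplaceParams(0, 1, 3)) == pytest.approx(0.75)

    def test_agrees_with_quadrature_of_pdf(self):
        p = SkewLaplaceParams(5.0, 0.02, 0.01)
        lo = p.mu - 40 / p.alpha
        for x in np.linspace(p.mu - 100, p.mu + 150, 20):
            num = integrate.quad(lambda t: sl_pdf(t, p), lo, x, limit=200,
                                 points=[p.mu] if lo < p.mu < x else None)[0]
            assert sl_cdf(x, p) == pytest.approx(num, abs=1e-8)

    def test_limits_and_monotone(self):
        p = SkewLaplaceParams(-3.0, 2.0, 0.5)
        grid = np.linspace(-60, 120, 400)
        F = np.asarray(sl_cdf(grid, p))
        assert np.all(np.diff(F) >= 0)
        assert F[0] < 1e-12 and F[-1] > 1 - 1e-12

    def test_nonfinite_x_rejected(self):
        with pytest.raises(ValueError):
            sl_cdf(np.inf, SkewLaplaceParams(0, 1, 1))


class TestQuantile:
    def test_symmetric_median_is_mu(self):
        assert sl_quantile(0.5, SkewLaplaceParams(7.0, 2.0, 2.0)) == pytest.approx(7.0)

    def test_round_trip_identity(self):
        # forward-scatter-like parameters: rod-shaped cells at 6 h
        p = SkewLaplaceParams(575.0, 0.023, 0.022)
        for prob in (0.01, 0.25, 0.5, 0.75, 0.99):
            assert sl_cdf(sl_quantile(prob, p), p) == pytest.approx(prob, rel=1e-12)

    def test_branch_point_maps_to_mu(self):
        p = SkewLaplaceParams(-2.0, 3.0, 1.0)
        assert sl_quantile(p.beta / (p.alpha + p.beta), p) == pytest.approx(p.mu, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.1, np.nan])
    def test_out_of_range_p_rejected(self, bad):
        with pytest.raises(ValueError):
            sl_quantile(bad, SkewLaplaceParams(0, 1, 1))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(params_st, st.floats(0.01, 0.99))
    def test_inverse_property(self, p, prob):
        assert sl_cdf(sl_quantile(prob, p), p) == pytest.approx(prob, rel=1e-9)


class TestMoments:
    def test_symmetric_mean_is_mu(self):
        mean, _ = sl_moments(SkewLaplaceParams(42.0, 0.7, 0.7))
        assert mean == pytest.approx(42.0)

    def test_direct_substitution(self):
        mean, var = sl_moments(SkewLaplaceParams(0, 1, 2))
        assert mean == pytest.approx(-0.5)
        assert var == pytest.approx(1.25)

    def test_against_quadrature(self):
        p = SkewLaplaceParams(3.0, 0.4, 1.2)
        mean, var = sl_moments(p)
        m1 = quad_split(lambda x: x * sl_pdf(x, p), p)
        m2 = quad_split(lambda x: (x - m1) ** 2 * sl_pdf(x, p), p)
        assert mean == pytest.approx(m1, rel=1e-6)
        assert var == pytest.approx(m2, rel=1e-6)

    def test_against_monte_carlo(self, saureus_ss_params):
        p = saureus_ss_params
        x = sl_sample(p, 1_000_000, seed=20240917)
        mean, var = sl_moments(p)
        se = np.sqrt(var / x.size)
        assert abs(x.mean() - mean) < 4 * se


class TestEntropy:
    def test_standard_laplace_value(self):
        # -∫ f ln f for the unit symmetric case is 1 + ln 2
        assert sl_entropy(SkewLaplaceParams(0, 1, 1)) == pytest.approx(1 + np.log(2), rel=1e-12)

    def test_location_invariance(self):
        a = sl_entropy(SkewLaplaceParams(0, 0.3, 2.0))
        b = sl_entropy(SkewLaplaceParams(123.4, 0.3, 2.0))
        assert a == b

    def test_peaked_case_value(self):
        assert sl_entropy(SkewLaplaceParams(0, 2, 2)) == pytest.approx(1.0)

    @pytest.mark.parametrize("p", [
        SkewLaplaceParams(0, 1, 1),
        SkewLaplaceParams(5, 0.2, 3.0),
        SkewLaplaceParams(-2, 4.0, 0.5),
    ])
    def test_matches_quadrature(self, p):
        num = quad_split(lambda x: -sl_pdf(x, p) * np.log(sl_pdf(x, p)), p)
        assert sl_entropy(p) == pytest.approx(num, abs=1e-6)


class TestSampling:
    def test_deterministic_given_seed(self, saureus_ss_params):
        a = sl_sample(saureus_ss_params, 1000, seed=5)
        b = sl_sample(saureus_ss_params, 1000, seed=5)
        assert np.array_equal(a, b)

    def test_left_mass_fraction(self):
        p = SkewLaplaceParams(0, 1, 3)
        n = 100_000
        x = sl_sample(p, n, seed=11)
        frac = np.mean(x <= p.mu)
        target = p.beta / (p.alpha + p.beta)
        assert abs(frac - target) < 4 * np.sqrt(target * (1 - target) / n)

    def test_empirical_variance_matches_formula(self):
        p = SkewLaplaceParams(0, 0.5, 0.25)
        x = sl_sample(p, 1_000_000, seed=13)
        _, var = sl_moments(p)
        # var of sample variance ~ (kurtosis) * var^2 / n; 6 sds is generous
        assert x.var() == pytest.approx(var, rel=0.02)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            sl_sample(SkewLaplaceParams(0, 1, 1), 0, seed=1)


class TestLogLinear:
    def test_slopes_read_off(self):
        (b0l, sl_), (b0r, sr) = sl_loglinear(SkewLaplaceParams(0, 2, 5))
        assert sl_ == pytest.approx(2.0)
        assert sr == pytest.approx(-5.0)

    def test_lines_intersect_at_mode(self):
        p = SkewLaplaceParams(3.5, 0.8, 1.9)
        (b0l, al), (b0r, ar) = sl_loglinear(p)
        peak = np.log(p.alpha * p.beta / (p.alpha + p.beta))
        assert b0l + al * p.mu == pytest.approx(peak, rel=1e-12)
        assert b0r + ar * p.mu == pytest.approx(peak, rel=1e-12)

    def test_lines_equal_log_pdf_on_each_side(self):
        # granule-rich side-scatter parameters: steep left, shallow right
        p = SkewLaplaceParams(427.0, 0.168, 0.016)
        (b0l, al), (b0r, ar) = sl_loglinear(p)
        xl = np.linspace(p.mu - 30, p.mu, 10)
        xr = np.linspace(p.mu + 1e-9, p.mu + 100, 10)
        assert np.allclose(b0l + al * xl, np.log(sl_pdf(xl, p)), rtol=1e-10)
        assert np.allclose(b0r + ar * xr, np.log(sl_pdf(xr, p)), rtol=1e-10)


class TestGammaModel:
    def test_normalizes_on_support(self):
        g = GammaModelParams(m0=0.5, gamma_shape=2.0, beta_rate=3.0)
        total = integrate.quad(lambda m: gamma_model_pdf(m, g), g.m0, np.inf, limit=200)[0]
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_reduces_to_exponential(self):
        g = GammaModelParams(m0=0.0, gamma_shape=0.0, beta_rate=2.0)
        m = np.linspace(0.01, 4, 25)
        assert np.allclose(gamma_model_pdf(m, g), 2.0 * np.exp(-2.0 * m), rtol=1e-10)

    def test_zero_at_minimum_size(self):
        g = GammaModelParams(m0=1.0, gamma_shape=1.5, beta_rate=2.0)
        assert gamma_model_pdf(1.0, g) == 0.0
        assert gamma_model_pdf(0.5, g) == 0.0  # below support, not an error

    @pytest.mark.parametrize("gamma_shape", [0.0, 0.5, 2.0, 7.0])
    def test_skewness_is_positive_and_matches_shifted_gamma(self, gamma_shape):
        # third standardized moment by quadrature of the explicit density
        from scipy.special import gamma as gamma_fn
        m0, beta = 0.3, 1.7
        U = np.exp(-beta * m0) * gamma_fn(gamma_shape + 1) * beta ** (-gamma_shape - 1)

        def dens(m):
            return (m - m0) ** gamma_shape * np.exp(-beta * m) / U

        hi = m0 + 60 * (gamma_shape + 1) / beta
        m1 = integrate.quad(lambda m: m * dens(m), m0, hi, limit=200)[0]
        m2 = integrate.quad(lambda m: (m - m1) ** 2 * dens(m), m0, hi, limit=200)[0]
        m3 = integrate.quad(lambda m: (m - m1) ** 3 * dens(m), m0, hi, limit=200)[0]
        skew = m3 / m2 ** 1.5
        assert skew > 0
        assert skew == pytest.approx(2.0 / np.sqrt(gamma_shape + 1.0), rel=1e-6)


class TestParamValidation:
    @pytest.mark.parametrize("kw", [
        {"mu": np.nan, "alpha": 1, "beta": 1},
        {"mu": 0, "alpha": 0, "beta": 1},
        {"mu": 0, "alpha": 1, "beta": -2},
    ])
    def test_invalid_skew_laplace_params(self, kw):
        with pytest.raises(ValueError):
            SkewLaplaceParams(**kw)

    def test_json_round_trip(self):
        p = SkewLaplaceParams(1.5, 0.2, 0.4)
        assert SkewLaplaceParams.from_dict(p.to_dict()) == p
        g = GammaModelParams(0.1, 2.0, 3.0)
        assert GammaModelParams.from_dict(g.to_dict()) == g
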