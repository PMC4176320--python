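"""Closed-form kinetics: examples, limits, and analytic identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from rcr import (
    ModelParams,
    TimeSeries,
    dsdna_rate,
    half_life,
    mass_ds,
    mass_ss,
    mass_total,
    predict,
    ss_peak_time,
    switched_fraction,
)

LAM = 1.95e-5


class TestModelParams:
    def test_consistent_n0_phi_accepted(self):
        p = ModelParams.from_n0_phi(lam=LAM, n0=3.0, phi=0.5)
        assert p.amplitude == 3.0

    def test_inconsistent_n0_phi_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ModelParams(lam=LAM, amplitude=1.0, n0=1.0, phi=1.0)

    @pytest.mark.parametrize("kw", [dict(lam=-1e-6, amplitude=1.0),
                                    dict(lam=LAM, amplitude=0.0),
                                    dict(lam=LAM, amplitude=-2.0)])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            ModelParams(**kw)

    def test_json_round_trip(self):
        p = ModelParams(lam=LAM, amplitude=0.5)
        q = ModelParams.from_json(p.to_json())
        assert (q.lam, q.amplitude) == (p.lam, p.amplitude)


class TestTimeSeries:
    def test_total_defaults_to_sum(self):
        ts = TimeSeries(times=[0.0, 1.0], ss_mass=[0.0, 2.0], ds_mass=[0.0, 1.0])
        np.testing.assert_allclose(ts.total_mass, [0.0, 3.0])

    @pytest.mark.parametrize(
        "kw",
        [
            dict(times=[1.0, 0.5], ss_mass=[0, 0], ds_mass=[0, 0]),
            dict(times=[-1.0, 0.5], ss_mass=[0, 0], ds_mass=[0, 0]),
            dict(times=[0.0, 1.0], ss_mass=[0, -1], ds_mass=[0, 0]),
            dict(times=[0.0, 1.0], ss_mass=[0, 1], ds_mass=[0, 1], total_mass=[0, 5]),
        ],
    )
    def test_invalid_series_rejected(self, kw):
        with pytest.raises(ValueError):
            TimeSeries(**kw)


class TestSwitchedFraction:
    def test_anchor_values(self):
        assert switched_fraction(0.0, LAM) == 0.0
        assert switched_fraction(math.log(2) / LAM, LAM) == pytest.approx(0.5)

    def test_against_monte_carlo_draws(self):
        # fraction of exponential switch times falling below t
        rng = np.random.default_rng(42)
        t = 86400.0
        draws = rng.exponential(1.0 / LAM, size=10**6)
        frac = float(np.mean(draws < t))
        se = math.sqrt(frac * (1 - frac) / 10**6)
        expected = switched_fraction(t, LAM)
        assert expected == pytest.approx(0.8145, abs=1e-3)
        assert abs(frac - expected) < 3 * se

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            switched_fraction(-1.0, LAM)
        with pytest.raises(ValueError):
            switched_fraction(1.0, -LAM)

    @given(st.floats(0.0, 1e7), st.floats(0.0, 1e7))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_time(self, t1, t2):
        lo, hi = sorted((t1, t2))
        assert switched_fraction(lo, LAM) <= switched_fraction(hi, LAM)


class TestRatesAndMasses:
    def test_dsdna_rate_boundaries(self, fitted_params):
        assert dsdna_rate(0.0, fitted_params) == 0.0
        assert dsdna_rate(1e9, fitted_params) == pytest.approx(0.0, abs=1e-12)

    def test_dsdna_rate_matches_quadrature(self, fitted_params):
        # rate = A * integral of the switching density over [t/2, t]
        t = 86400.0
        lam = fitted_params.lam
        integral, _ = quad(lambda s: lam * math.exp(-lam * s), t / 2, t,
                           epsrel=1e-12)
        assert dsdna_rate(t, fitted_params) == pytest.approx(
            fitted_params.amplitude * integral, rel=1e-8
        )

    def test_dsdna_rate_cdf_identity(self, fitted_params, dense_grid):
        # r_ds(t) = A * [F(t) - F(t/2)] with F the switching CDF
        lam = fitted_params.lam
        expected = fitted_params.amplitude * (
            switched_fraction(dense_grid, lam) - switched_fraction(dense_grid / 2, lam)
        )
        np.testing.assert_allclose(dsdna_rate(dense_grid, fitted_params), expected,
                                   rtol=1e-12, atol=1e-15)

    def test_mass_ds_is_integral_of_rate(self, fitted_params):
        t = 3600.0
        integral, _ = quad(lambda s: dsdna_rate(s, fitted_params), 0.0, t,
                           epsrel=1e-12)
        assert mass_ds(t, fitted_params) == pytest.approx(integral, rel=1e-8)

    def test_mass_ds_plateau(self, fitted_params):
        assert mass_ds(0.0, fitted_params) == 0.0
        assert mass_ds(1e9, fitted_params) == pytest.approx(1 / LAM, rel=1e-6)

    def test_mass_ss_boundaries(self, fitted_params):
        assert mass_ss(0.0, fitted_params) == 0.0
        assert mass_ss(1e9, fitted_params) == pytest.approx(0.0, abs=1e-9)

    def test_mass_ss_small_lam_is_linear_production(self):
        # with n0*phi = 1 and no switching, production is 1 mass unit/s
        p = ModelParams.from_n0_phi(lam=0.0, n0=1.0, phi=1.0)
        assert mass_ss(100.0, p) == pytest.approx(100.0)
        assert mass_ds(100.0, p) == 0.0

    def test_negative_time_rejected(self, fitted_params):
        for fn in (mass_ss, mass_ds, mass_total, dsdna_rate):
            with pytest.raises(ValueError):
                fn(-1.0, fitted_params)


class TestDerivedQuantities:
    def test_half_life_anchor(self):
        # ln2 / 1.95e-5 = 35,546 s = 9.87 h, reported rounded as 9.9 h
        hl = half_life(LAM)
        assert hl == pytest.approx(35546, abs=1)
        assert hl / 3600 == pytest.approx(9.9, abs=0.05)

    def test_half_life_definition_and_median(self):
        assert half_life(math.log(2)) == pytest.approx(1.0)
        assert half_life(1e-5) == pytest.approx(69315, abs=1)
        rng = np.random.default_rng(7)
        med = np.median(rng.exponential(1e5, size=10**6))
        assert med == pytest.approx(half_life(1e-5), rel=5e-3)

    def test_ss_peak_time_matches_numerical_maximum(self, fitted_params):
        peak = ss_peak_time(LAM)
        assert peak == pytest.approx(2 * math.log(2) / LAM)
        res = minimize_scalar(lambda t: -mass_ss(t, fitted_params),
                              bounds=(1.0, 1e6), method="bounded",
                              options={"xatol": 0.01})
        assert abs(res.x - peak) < 1.0
        assert mass_ss(peak, fitted_params) == pytest.approx(-res.fun, rel=1e-9)

    @pytest.mark.parametrize("fn", [half_life, ss_peak_time])
    def test_nonpositive_rate_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(0.0)


class TestPredictAndInvariants:
    def test_predict_at_origin(self, fitted_params):
        ts = predict([0.0], fitted_params)
        assert ts.ss_mass[0] == 0.0 and ts.ds_mass[0] == 0.0

    def test_conservation_identity(self, fitted_params, dense_grid):
        # N_ss + N_ds = (A/lam)(1 - exp(-lam t/2)) to machine precision
        ts = predict(dense_grid[1:], fitted_params)
        lam, amp = fitted_params.lam, fitted_params.amplitude
        expected = -(amp / lam) * np.expm1(-lam * dense_grid[1:] / 2)
        np.testing.assert_allclose(ts.ss_mass + ts.ds_mass, expected, rtol=1e-12)
        np.testing.assert_allclose(mass_total(dense_grid[1:], fitted_params),
                                   expected, rtol=1e-12)

    def test_monotonicity_and_bounds(self, fitted_params, dense_grid):
        ts = predict(dense_grid, fitted_params)
        assert np.all(np.diff(ts.ds_mass) >= 0)
        assert np.all(np.diff(ts.total_mass) >= 0)
        assert np.all(ts.ds_mass <= fitted_params.plateau + 1e-12)

    def test_ss_unimodality(self, fitted_params):
        peak = ss_peak_time(LAM)
        before = np.linspace(1.0, peak, 400)
        after = np.linspace(peak, 20 * peak, 400)
        assert np.all(np.diff(mass_ss(before, fitted_params)) > 0)
        assert np.all(np.diff(mass_ss(after, fitted_params)) < 0)

    def test_curves_cross_once(self, fitted_params, dense_grid):
        # ss starts above ds, ds ends above ss, exactly one sign change
        ts = predict(dense_grid[1:], fitted_params)
        sign = np.sign(ts.ss_mass - ts.ds_mass)
        changes = np.sum(np.diff(sign) != 0)
        assert changes == 1

    def test_small_lam_limits(self):
        # lam -> 0 with n0*phi fixed: ss -> n0*phi*t, ds/t^2 -> n0*phi*lam/2
        lam = 1e-12
        p = ModelParams.from_n0_phi(lam=lam, n0=1.0, phi=1.0)
        t = 1000.0
        assert mass_ss(t, p) == pytest.approx(t, rel=1e-3)
        assert mass_ds(t, p) / t**2 == pytest.approx(lam / 2, rel=1e-3)

    def test_unsorted_times_rejected(self, fitted_params):
        with pytest.raises(ValueError):
            predict([10.0, 5.0], fitted_params)
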