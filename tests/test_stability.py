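"""Lambert-W spectral analysis against brute-force and simulation oracles."""

import cmath
import math

import numpy as np
import pytest

from nfkbloop.dde import integrate
from nfkbloop.params import InputSignal, ModelParams, persistent
from nfkbloop.stability import (
    dominant_eigenvalue,
    fixed_point,
    fixed_point_large_k,
    linear_coefficients,
    measure_oscillations,
    period_sensitivity,
    summarize_series,
)


class TestFixedPoint:
    def test_rhs_vanishes_at_fixed_point(self, simple_params):
        from nfkbloop.model import rhs_single

        for k in (0.5, 1.0, 3.0):
            y_star = fixed_point(simple_params, k)
            assert abs(rhs_single(y_star, y_star, k, simple_params)) < 1e-10

    def test_explicit_large_k_matches_numeric_root(self, simple_params):
        """In the strongly stimulated regime the explicit stationary level
        agrees with the numeric root of the full balance within 2%."""
        for k in (2.0, 4.0, 8.0):
            explicit = fixed_point_large_k(simple_params, k)
            numeric = fixed_point(simple_params, k)
            assert explicit == pytest.approx(numeric, rel=0.02)

    def test_stationary_level_decreases_with_input(self, simple_params):
        ys = [fixed_point(simple_params, k) for k in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a > b for a, b in zip(ys, ys[1:]))


class TestDominantEigenvalue:
    def test_no_delayed_term_gives_minus_a(self, simple_params):
        p = simple_params.with_(c1=0.0)  # b = 0: pure exponential relaxation
        r = dominant_eigenvalue(p, 1.0)
        assert r.b == 0.0
        assert r.eigenvalue == pytest.approx(complex(-r.a, 0.0))
        assert math.isnan(r.period)

    def test_branch_point_is_real_double_root(self, simple_params):
        """Where the Lambert argument reaches -1/e the two real roots merge:
        the returned eigenvalue is real and the period is undefined."""
        p = simple_params.with_(tau1=20.0)
        # tune c1 so -b*tau*exp(a*tau) sits essentially at the branch point
        from scipy.optimize import brentq

        from nfkbloop.stability import linear_coefficients

        def arg_of(c1):
            a, b, _ = linear_coefficients(p.with_(c1=c1), 1.0)
            return -b * p.tau1 * math.exp(a * p.tau1) + 1.0 / math.e

        c1_star = brentq(arg_of, 1.0, 18.0, xtol=1e-10)
        r = dominant_eigenvalue(p.with_(c1=c1_star), 1.0)
        assert abs(r.eigenvalue.imag) < 1e-3
        assert math.isnan(r.period)
        # W(-1/e) = -1, so the eigenvalue sits at -a - 1/tau
        assert r.eigenvalue.real == pytest.approx(-r.a - 1.0 / p.tau1, rel=1e-3)

    def test_characteristic_residual(self, simple_params):
        for k in (0.5, 1.0, 2.0, 5.0):
            r = dominant_eigenvalue(simple_params, k)
            assert r.residual() < 1e-9

    def test_rightmost_root_against_newton_grid_oracle(self, simple_params):
        """Brute-force spectral oracle: Newton iteration from a complex grid
        must find no root to the right of the Lambert-W eigenvalue."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            k = rng.uniform(0.3, 5.0)
            tau = rng.uniform(15.0, 60.0)
            p = simple_params.with_(tau1=tau)
            r = dominant_eigenvalue(p, k)
            a, b, tau_ = r.a, r.b, r.tau

            def char(lam):
                return lam + a + b * cmath.exp(-lam * tau_)

            def char_prime(lam):
                return 1 - b * tau_ * cmath.exp(-lam * tau_)

            best = -np.inf
            for re in np.linspace(-0.5, 0.3, 20):
                for im in np.linspace(0.01, 0.5, 20):
                    lam = complex(re, im)
                    try:
                        for _ in range(60):
                            step = char(lam) / char_prime(lam)
                            lam -= step
                            if abs(step) < 1e-13:
                                break
                        if abs(char(lam)) < 1e-9:
                            best = max(best, lam.real)
                    except (OverflowError, ZeroDivisionError):
                        continue  # Newton escaped toward Re λ → -inf
            assert best <= r.eigenvalue.real + 1e-6

    def test_analytic_period_matches_simulation(self, simple_params):
        """2π/Im λ agrees with the inter-peak interval of the nonlinear DDE."""
        r = dominant_eigenvalue(simple_params, 1.0)
        traj = integrate("single", simple_params, persistent(1.0), 600.0)
        s = measure_oscillations(traj, t_cut=0.0)
        assert s.period == pytest.approx(r.period, rel=0.05)


class TestPeriodSensitivity:
    def test_delay_doubling_shifts_period_strongly(self, simple_params):
        tab = period_sensitivity(simple_params, [1.0], [30.0, 60.0])
        p30, p60 = tab.sort_values("tau_min")["period_min"].to_numpy()
        assert p60 > 1.5 * p30

    def test_input_quadrupling_shifts_period_weakly(self, ref):
        tab = period_sensitivity(ref, [1.0, 4.0], [ref.tau1])
        periods = tab["period_min"].to_numpy()
        assert abs(periods[1] - periods[0]) / periods[0] < 0.10

    def test_decay_monotone_and_locally_linear_in_input(self, ref):
        """The decay rate grows monotonically with the input; in the
        moderate-stimulation window, where the instantaneous removal term
        dominates the eigenvalue shift, the growth is linear."""
        ks_wide = np.linspace(0.25, 8.0, 12)
        dec_wide = period_sensitivity(ref, ks_wide, [ref.tau1])["decay_per_min"].to_numpy()
        assert np.all(np.diff(dec_wide) > 0)
        ks = np.linspace(0.1, 0.5, 9)
        dec = period_sensitivity(ref, ks, [ref.tau1])["decay_per_min"].to_numpy()
        assert np.corrcoef(ks, dec)[0, 1] ** 2 > 0.99


class TestMeasureOscillations:
    def test_constructed_damped_cosine(self):
        t = np.linspace(0.0, 600.0, 6001)
        x = 100 * np.exp(-t / 200.0) * (1 + 0.5 * np.cos(2 * np.pi * t / 90.0))
        s = summarize_series(t, x, prominence=1.0)
        assert s.period == pytest.approx(90.0, abs=1.0)

    def test_constant_trajectory_has_no_peaks(self):
        t = np.linspace(0.0, 500.0, 501)
        s = summarize_series(t, np.full_like(t, 42.0), prominence=1.0)
        assert s.n_peaks == 0
        assert math.isnan(s.period)
        assert s.max_peak_trough_after(0.0) == 0.0

    def test_decay_estimate_against_linearization(self, simple_params):
        """Measured amplitude decay of a small perturbation matches -Re λ."""
        p = simple_params.with_(c1=25.0, r_ikk=0.18)  # clearly damped regime
        r = dominant_eigenvalue(p, 1.0, form="full")
        y_star = fixed_point(p, 1.0)
        sig = InputSignal(amplitude=1.0, t_on=0.0, baseline=1.0)
        traj = integrate("single", p, sig, 600.0, history=(1.02 * y_star, 0.0))
        samp = traj.sample(dt=0.1)
        s = summarize_series(samp["time_min"], samp["x_nM"],
                             prominence=1e-4 * p.nf_tot)
        assert s.decay == pytest.approx(r.decay_rate, rel=0.15)
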