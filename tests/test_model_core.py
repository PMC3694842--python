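"""Quasi-equilibrium algebra and right-hand-side contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nfkbloop.model import (
    complex_fractions,
    free_nfkb_fixed_point_iteration,
    promoter_occupancy,
    rhs_dual,
    rhs_single,
    solve_free_nfkb,
)
from nfkbloop.params import ModelParams, no_feedback_variant


class TestPromoterOccupancy:
    @pytest.mark.parametrize(
        "x_over_kp, expected_bound",
        [(0.0, 0.0), (1.0, 0.5), (9.0, 0.9)],
    )
    def test_hyperbolic_saturation(self, x_over_kp, expected_bound):
        kp = 30.0
        p_free, p_bound = promoter_occupancy(x_over_kp * kp, kp)
        assert p_bound == pytest.approx(expected_bound, abs=1e-12)
        assert p_free + p_bound == pytest.approx(1.0, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            promoter_occupancy(-1.0, 30.0)
        with pytest.raises(ValueError):
            promoter_occupancy(1.0, 0.0)

    @given(x=st.floats(0, 1e4), x2=st.floats(0, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_x(self, x, x2):
        lo, hi = sorted((x, x2))
        assert promoter_occupancy(lo, 10.0)[1] <= promoter_occupancy(hi, 10.0)[1]


class TestFreeNFkB:
    def test_no_inhibitor_all_free(self, simple_params):
        assert solve_free_nfkb(0.0, 0.0, simple_params) == pytest.approx(
            simple_params.nf_tot, rel=1e-12
        )

    def test_strong_sequestration_limit(self, simple_params):
        xs = [solve_free_nfkb(y, 0.0, simple_params) for y in (1e3, 1e5, 1e7)]
        assert xs[0] > xs[1] > xs[2]
        assert xs[-1] < 1e-2

    @given(
        y_a=st.floats(0, 2000),
        y_e=st.floats(0, 2000),
    )
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_fixed_point_iteration(self, y_a, y_e):
        p = ModelParams(
            nf_tot=125.0, c0=0.0, c1=0.0, deg_a=0.1, r_ikk=0.1, rho=1.0,
            kp=30.0, kc=2.0, tau1=10.0, tau2=10.0,
        )
        direct = solve_free_nfkb(y_a, y_e, p)
        oracle = free_nfkb_fixed_point_iteration(y_a, y_e, p)
        assert direct == pytest.approx(oracle, rel=1e-8, abs=1e-10)

    @given(y=st.floats(0, 3000), dy=st.floats(1e-3, 100))
    @settings(max_examples=60, deadline=None)
    def test_strictly_decreasing_in_inhibitor(self, y, dy):
        p = ModelParams(
            nf_tot=125.0, c0=0.0, c1=0.0, deg_a=0.1, r_ikk=0.1, rho=1.0,
            kp=30.0, kc=2.0, tau1=10.0, tau2=10.0,
        )
        assert solve_free_nfkb(y + dy, 0.0, p) < solve_free_nfkb(y, 0.0, p)

    def test_conservation_reconstruction(self, simple_params):
        """Free NF-κB plus sequestered NF-κB reconstructs the total."""
        p = simple_params
        for y_a, y_e in [(50.0, 0.0), (200.0, 80.0), (10.0, 500.0)]:
            x = solve_free_nfkb(y_a, y_e, p)
            _, f_bound = complex_fractions(x, p)
            total = x + (y_a + y_e) * f_bound
            assert total == pytest.approx(p.nf_tot, rel=1e-8)


class TestRightHandSides:
    def test_dual_reduces_to_single_bitwise(self, simple_params):
        p = simple_params.with_(eps=0.0)
        for y, yd, k in [(50.0, 60.0, 1.0), (200.0, 30.0, 0.0), (0.0, 0.0, 2.0)]:
            dya, dye = rhs_dual((y, 0.0), (yd, 0.0), (yd, 0.0), k, p)
            assert dye == 0.0
            assert rhs_single(y, yd, k, p) == dya  # identical evaluation order

    def test_zero_at_basal_steady_state(self, simple_params):
        from nfkbloop.dde import basal_state

        ya, ye = basal_state(simple_params, 0.0)
        d = rhs_single(ya, ya, 0.0, simple_params)
        assert abs(d) < 1e-9

    def test_matches_full_mass_action_oracle(self):
        """The reduced RHS equals the slow dynamics of the unreduced system.

        The oracle builds the full mass-action network (free inhibitor,
        complex, promoter states) with fast binding, relaxes the fast
        reactions to equilibrium at fixed totals, and sums the slow
        (synthesis/degradation) fluxes for the total inhibitor pools.
        """
        p = ModelParams(
            nf_tot=125.0, c0=0.5, c1=20.0, deg_a=0.1, r_ikk=0.3, rho=0.8,
            kp=40.0, kc=3.0, tau1=30.0, tau2=40.0, eps=0.6, c0_e=0.05, deg_e=0.25,
        )
        rng = np.random.default_rng(42)
        for _ in range(20):
            y_a, y_e = rng.uniform(0, 400, size=2)
            d1 = rng.uniform(0, 400, size=2)
            d2 = rng.uniform(0, 400, size=2)
            k = rng.uniform(0, 2)

            def parts(ya, ye):
                x = solve_free_nfkb(ya, ye, p)
                f_free, f_bound = complex_fractions(x, p)
                return x, (ya * f_free, ya * f_bound), (ye * f_free, ye * f_bound)

            x_now, (af, ab), (ef, eb) = parts(y_a, y_e)
            x_d1, _, _ = parts(*d1)
            x_d2, _, _ = parts(*d2)
            pf1, pb1 = promoter_occupancy(x_d1, p.kp)
            pf2, pb2 = promoter_occupancy(x_d2, p.kp)
            # slow fluxes of the full system, summed over free + complex
            dya_full = (
                p.c0 * pf1 + p.c1 * pb1
                - p.deg_a * af
                - p.r_ikk * k * (af + p.rho * ab)
            )
            dye_full = (
                p.eps * (p.c0_e * pf2 + p.c1 * pb2)
                - p.deg_e * ef
                - p.r_ikk * k * (ef + p.rho * eb)
            )
            dya, dye = rhs_dual((y_a, y_e), tuple(d1), tuple(d2), k, p)
            assert dya == pytest.approx(dya_full, rel=1e-12)
            assert dye == pytest.approx(dye_full, rel=1e-12)


class TestNoFeedbackVariant:
    def test_disables_induced_synthesis(self, simple_params):
        v = no_feedback_variant(simple_params)
        assert v.c1 == 0.0 and v.constitutive_only
        # synthesis is promoter-independent: rhs no longer depends on delayed state
        assert rhs_single(50.0, 10.0, 1.0, v) == rhs_single(50.0, 400.0, 1.0, v)

    def test_constitutive_rate_override(self, simple_params):
        v = no_feedback_variant(simple_params, c0=0.3)
        assert v.c0 == 0.3

    def test_non_oscillatory_under_persistent_input(self, ref):
        from nfkbloop.dde import integrate
        from nfkbloop.params import persistent
        from nfkbloop.stability import measure_oscillations

        traj = integrate("none", ref, persistent(1.0), 600.0)
        s = measure_oscillations(traj, t_cut=0.0)
        assert s.n_peaks <= 1

    def test_higher_constitutive_rate_attenuates_faster(self, ref):
        """Raising constitutive synthesis from 0.00185 to 0.3 nM/min speeds
        post-pulse shutdown of the feedback-free module."""
        from nfkbloop.dde import integrate
        from nfkbloop.params import pulse

        def time_below(c0):
            traj = integrate("none", ref.with_(c0=c0), pulse(1.0, 15.0), 2000.0)
            t = np.arange(20.0, 2000.0, 0.5)
            x = traj.x(t)
            peak = x.max()
            below = t[x < 0.5 * peak]
            return below[0] if below.size else np.inf

        assert time_below(0.3) < time_below(0.00185)
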