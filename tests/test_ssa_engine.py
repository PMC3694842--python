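"""Delayed stochastic simulation: exactness, conservation, determinism."""

import numpy as np
import pytest
from scipy import stats

from nfkbloop.params import InputSignal, ModelParams, persistent
from nfkbloop.ssa import (
    AutoRepressorParams,
    build_network,
    cv_peak_and_late,
    ensemble,
    simulate,
)


@pytest.fixture(scope="module")
def ssa_params(request):
    return request.getfixturevalue("ref")


def _birth_death_network(birth=40.0, death=0.4, delay=0.0):
    """Minimal hand-built network: ∅ -> N at `birth`, N -> ∅ at `death`."""
    from nfkbloop.ssa import ReactionNetwork

    return ReactionNetwork(
        architecture="none",
        species=["N"],
        rate=np.array([birth, death]),
        ri1=np.array([-1, 0], dtype=np.int64),
        ri2=np.array([-1, -1], dtype=np.int64),
        k_dep=np.array([0, 0], dtype=np.uint8),
        delay=np.array([delay, 0.0]),
        stoich_now=np.array([[0 if delay > 0 else 1], [-1]], dtype=np.int64),
        stoich_done=np.array([[1 if delay > 0 else 0], [0]], dtype=np.int64),
        omega=1.0,
        init=np.array([0], dtype=np.int64),
        output="N",
        params=AutoRepressorParams(),
    )


class TestExactness:
    def test_birth_death_stationary_mean(self):
        """Stationary mean of a birth-death process is birth/death."""
        net = _birth_death_network()
        sig = persistent(1.0)
        finals = [simulate(net, sig, 100.0, seed=1000 + i).series("N")[-1]
                  for i in range(200)]
        target = 40.0 / 0.4
        se = np.std(finals, ddof=1) / np.sqrt(len(finals))
        assert abs(np.mean(finals) - target) < 3 * se

    def test_birth_death_stationary_distribution_poisson(self):
        """Chi-square against the Poisson stationary law at a fixed seed set."""
        net = _birth_death_network(birth=12.0, death=0.6)
        sig = persistent(1.0)
        lam = 20.0
        finals = np.array([simulate(net, sig, 60.0, seed=5000 + i).series("N")[-1]
                           for i in range(300)])
        edges = [0, 14, 17, 20, 23, 26, 1000]
        obs = np.histogram(finals, bins=edges)[0]
        cdf = stats.poisson(lam).cdf
        probs = np.diff([cdf(e - 1) for e in edges])
        chi2 = ((obs - 300 * probs) ** 2 / (300 * probs)).sum()
        p = 1 - stats.chi2(len(obs) - 1).cdf(chi2)
        assert p > 0.01

    def test_delayed_birth_produces_nothing_before_delay(self):
        net = _birth_death_network(birth=100.0, death=0.0, delay=12.0)
        tr = simulate(net, persistent(1.0), 30.0, seed=7, grid_dt=0.5)
        before = tr.series("N")[tr.times < 12.0]
        after = tr.series("N")[tr.times > 13.0]
        assert np.all(before == 0)
        assert after[-1] > 0


class TestNetworks:
    def test_none_architecture_has_no_promoter(self, ssa_params):
        net = build_network("none", ssa_params, 1000)
        assert not any(s.startswith("G") for s in net.species)

    def test_dual_with_eps_zero_has_silent_eps_synthesis(self, ssa_params):
        net = build_network("dual", ssa_params.with_(eps=0.0), 1000)
        state = net.init.copy()
        state[net.index("Ge_bound")] = 1
        state[net.index("Ge_free")] = 0
        a = net.propensities(state, 1.0)
        zf = net.index("Zf")
        eps_synth = [r for r in range(net.n_reactions)
                     if net.delay[r] > 0 and net.stoich_done[r, zf] > 0]
        assert len(eps_synth) == 2
        assert all(a[r] == 0.0 for r in eps_synth)

    def test_unknown_architecture_rejected(self, ssa_params):
        with pytest.raises(ValueError):
            build_network("ring-oscillator", ssa_params, 1000)

    def test_propensities_reproduce_deterministic_rhs(self, ssa_params):
        """Rate-equation limit: summed propensity fluxes for total IκBα,
        divided by omega, equal the reduced RHS at quasi-equilibrium."""
        from nfkbloop.model import complex_fractions, rhs_single, solve_free_nfkb

        p = ssa_params.with_(eps=0.0)
        net = build_network("single", p, 100_000)  # large copy number limit
        omega = net.omega
        rng = np.random.default_rng(0)
        for _ in range(10):
            y_tot = rng.uniform(20.0, 400.0)
            k = rng.uniform(0.0, 2.0)
            x = solve_free_nfkb(y_tot, 0.0, p)
            f_free, f_bound = complex_fractions(x, p)
            state = np.zeros(net.n_species)
            state[net.index("X")] = x * omega
            state[net.index("Yf")] = y_tot * f_free * omega
            state[net.index("Yc")] = y_tot * f_bound * omega
            # promoter at quasi-equilibrium occupancy (average state)
            pb = x / (p.kp + x)
            state[net.index("Ga_free")] = 1 - pb
            state[net.index("Ga_bound")] = pb
            a = net.propensities(state, k)
            yf, yc = net.index("Yf"), net.index("Yc")
            flux = sum(
                a[r] * (net.stoich_now[r, yf] + net.stoich_now[r, yc]
                        + net.stoich_done[r, yf] + net.stoich_done[r, yc])
                for r in range(net.n_reactions)
            )
            # delayed-state argument equals instantaneous state here
            assert flux / omega == pytest.approx(rhs_single(y_tot, y_tot, k, p), rel=1e-9)

    def test_nfkb_conservation_every_sample(self, ssa_params):
        net = build_network("dual", ssa_params, 1000)
        tr = simulate(net, InputSignal(amplitude=1.0, t_on=30.0), 200.0, seed=11)
        total = (tr.series("X") + tr.series("Yc") + tr.series("Zc")
                 + tr.series("Ga_bound") + tr.series("Ge_bound"))
        assert np.all(total == 1000)

    def test_promoter_occupancy_is_binary(self, ssa_params):
        net = build_network("single", ssa_params, 1000)
        tr = simulate(net, persistent(1.0), 100.0, seed=3)
        g = tr.series("Ga_bound")
        assert set(np.unique(g)) <= {0, 1}


class TestDeterminismAndEnsembles:
    def test_identical_seed_bit_identical(self, ssa_params):
        net = build_network("single", ssa_params, 1000)
        sig = InputSignal(amplitude=1.0, t_on=60.0)
        a = simulate(net, sig, 300.0, seed=42)
        b = simulate(net, sig, 300.0, seed=42)
        assert a.n_events == b.n_events
        assert np.array_equal(a.counts, b.counts)

    def test_ensemble_requires_two_runs(self, ssa_params):
        net = build_network("single", ssa_params, 1000)
        with pytest.raises(ValueError):
            ensemble(net, persistent(1.0), 50.0, 1, seed=0)

    def test_cv_zero_for_identical_family(self):
        t = np.arange(0.0, 300.0, 1.0)
        x = 100 * np.exp(-t / 100) * (1 + 0.4 * np.cos(2 * np.pi * t / 90)) + 5
        fam = np.tile(x, (5, 1))
        cv_p, cv_l = cv_peak_and_late(t, fam)
        assert cv_p == pytest.approx(0.0, abs=1e-12)
        assert cv_l == pytest.approx(0.0, abs=1e-12)

    def test_cv_peak_of_scaled_family_matches_amplitude_scatter(self):
        """Pure amplitude scatter with common phase: the peak CV equals the
        CV of the scale factors (closed form for scaled signals)."""
        rng = np.random.default_rng(1)
        t = np.arange(0.0, 400.0, 1.0)
        base = 100 * np.exp(-t / 300) * (1 + 0.5 * np.cos(2 * np.pi * t / 90)) + 10
        scales = 1 + 0.1 * rng.standard_normal(40)
        fam = np.outer(scales, base)
        cv_p, _ = cv_peak_and_late(t, fam)
        expected = np.std(scales, ddof=1) / np.mean(scales)
        assert cv_p == pytest.approx(expected, rel=1e-9)
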