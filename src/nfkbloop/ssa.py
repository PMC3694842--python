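"""Discrete stochastic versions of the feedback architectures.

Networks are built from the same kinetic parameters as the deterministic
models, converted to stochastic propensities through the system size
``omega = n_nfkb_total / nf_tot`` (molecules per nM). Binding steps that
the deterministic reduction eliminates by quasi-equilibrium (promoter
occupancy, IκB–NF-κB association) are simulated explicitly here with fast
association/dissociation rates consistent with the equilibrium constants.
Delayed synthesis follows the Bratsun scheme: initiation at the current
propensity, product update one delay later, nothing consumed at
initiation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._ssa_core import run_ssa
from .dde import basal_state
from .model import solve_free_nfkb
from .params import InputSignal, ModelParams

__all__ = [
    "ReactionNetwork",
    "StochTrajectory",
    "EnsembleSummary",
    "AutoRepressorParams",
    "build_network",
    "simulate",
    "ensemble",
    "cv_peak_and_late",
]

ARCHITECTURES = ("none", "single", "dual", "autorepressor")

#: default association rate for IκB–NF-κB and NF-κB–promoter binding,
#: 1/(nM min); fast against the minutes-scale turnover so the discrete
#: system stays near the binding quasi-equilibrium the reduction assumes.
BINDING_ON_RATE = 0.5

#: promoter binding rate, 1/(nM min). Chosen fast (sub-minute dwell times,
#: consistent with FRAP measurements of second-scale transcription-factor
#: residence) so promoter flicker is well averaged and synthesis is not
#: artificially bursty.
PROMOTER_ON_RATE = 3.0


@dataclass(frozen=True)
class AutoRepressorParams:
    """A transcription-based alternative circuit: a self-repressing gene.

    The input activates delayed synthesis of a repressor from the unbound
    promoter; the repressor binds its own promoter and shuts synthesis
    off. Signaling here relies on protein production rather than on the
    release of a sequestered pool.
    """

    synthesis: float = 36.0  # molecules/min at K = 1 from the unbound promoter
    degradation: float = 0.03  # 1/min
    on_rate: float = 1e-4  # repressor-promoter binding, 1/(molecule min)
    off_rate: float = 0.02  # unbinding, 1/min
    delay: float = 45.0  # synthesis delay, min


@dataclass
class ReactionNetwork:
    """Delayed-reaction network in the array form the SSA core consumes."""

    architecture: str
    species: list[str]
    rate: np.ndarray
    ri1: np.ndarray
    ri2: np.ndarray
    k_dep: np.ndarray
    delay: np.ndarray
    stoich_now: np.ndarray
    stoich_done: np.ndarray
    omega: float
    init: np.ndarray
    output: str  # species whose count is the circuit output
    params: ModelParams | AutoRepressorParams = field(repr=False)
    #: continuous basal mean state (fractional promoter occupancy) used to
    #: warm-start the delayed-synthesis pipeline at its stationary rate
    mean_state: np.ndarray | None = None

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.rate)

    def index(self, name: str) -> int:
        return self.species.index(name)

    def propensities(self, state, k: float) -> np.ndarray:
        """Propensity vector at a state (reference implementation)."""
        state = np.asarray(state)
        a = self.rate.copy()
        for r in range(self.n_reactions):
            if self.ri1[r] >= 0:
                a[r] *= state[self.ri1[r]]
            if self.ri2[r] >= 0:
                a[r] *= state[self.ri2[r]]
            if self.k_dep[r]:
                a[r] *= k
        return a


@dataclass
class StochTrajectory:
    """One delayed-SSA realization sampled on a uniform grid."""

    times: np.ndarray
    counts: np.ndarray  # (n_times, n_species)
    species: list[str]
    seed: int
    n_events: int

    def series(self, name: str) -> np.ndarray:
        return self.counts[:, self.species.index(name)]


@dataclass
class EnsembleSummary:
    """Per-time mean, standard deviation and CV across runs."""

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_runs: int

    @property
    def cv(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.mean > 0, self.sd / self.mean, np.nan)


class _Builder:
    def __init__(self, species: list[str]):
        self.species = species
        self.idx = {s: i for i, s in enumerate(species)}
        self.rows: list[tuple] = []

    def add(self, rate, reactants, changes_now, changes_done=None, k_dep=False, delay=0.0):
        ri = [self.idx[s] for s in reactants]
        ri += [-1] * (2 - len(ri))
        now = np.zeros(len(self.species), dtype=np.int64)
        for s, d in (changes_now or {}).items():
            now[self.idx[s]] = d
        done = np.zeros(len(self.species), dtype=np.int64)
        for s, d in (changes_done or {}).items():
            done[self.idx[s]] = d
        self.rows.append((float(rate), ri[0], ri[1], bool(k_dep), float(delay), now, done))

    def build(self, architecture, omega, init, output, params, mean_state=None) -> ReactionNetwork:
        n = len(self.rows)
        return ReactionNetwork(
            mean_state=mean_state,
            architecture=architecture,
            species=self.species,
            rate=np.array([r[0] for r in self.rows]),
            ri1=np.array([r[1] for r in self.rows], dtype=np.int64),
            ri2=np.array([r[2] for r in self.rows], dtype=np.int64),
            k_dep=np.array([r[3] for r in self.rows], dtype=np.uint8),
            delay=np.array([r[4] for r in self.rows]),
            stoich_now=np.stack([r[5] for r in self.rows]) if n else np.zeros((0, len(self.species)), np.int64),
            stoich_done=np.stack([r[6] for r in self.rows]) if n else np.zeros((0, len(self.species)), np.int64),
            omega=omega,
            init=np.asarray(init, dtype=np.int64),
            output=output,
            params=params,
        )


def build_network(
    architecture: str,
    params: ModelParams | AutoRepressorParams,
    n_nfkb_total: int = 1000,
    binding_on_rate: float | None = None,
    promoter_on_rate: float | None = None,
) -> ReactionNetwork:
    """Construct the discrete network for one architecture.

    For the NF-κB architectures total NF-κB is conserved structurally:
    every reaction that consumes free NF-κB produces exactly one bound
    form (complex or occupied promoter) and vice versa. Initial counts are
    the basal deterministic steady state rounded to integers, with free
    NF-κB set by the conservation law so the total is exact.

    ``binding_on_rate`` and ``promoter_on_rate`` override the module
    defaults. They are fidelity knobs of the stochastic layer, not model
    parameters: the reduced models eliminate these steps by
    quasi-equilibrium, so faster rates track the reduction more closely
    at higher event cost. Quantitative SSA-vs-DDE comparisons should use
    fast rates; long qualitative ensembles tolerate the defaults.
    """
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}; expected one of {ARCHITECTURES}")
    if architecture == "autorepressor":
        ap = params if isinstance(params, AutoRepressorParams) else AutoRepressorParams()
        b = _Builder(["R", "G_free", "G_bound"])
        b.add(ap.on_rate, ["R", "G_free"], {"R": -1, "G_free": -1, "G_bound": +1})
        b.add(ap.off_rate, ["G_bound"], {"R": +1, "G_free": +1, "G_bound": -1})
        b.add(ap.degradation, ["R"], {"R": -1})
        b.add(ap.synthesis, ["G_free"], {}, {"R": +1}, k_dep=True, delay=ap.delay)
        init = np.array([0, 1, 0])
        return b.build(architecture, 1.0, init, "R", ap,
                       mean_state=np.array([0.0, 1.0, 0.0]))

    p = params
    if not isinstance(p, ModelParams):
        raise TypeError("NF-κB architectures require ModelParams")
    if n_nfkb_total < 10:
        raise ValueError("n_nfkb_total must be at least 10")
    omega = n_nfkb_total / p.nf_tot

    kon = binding_on_rate if binding_on_rate is not None else BINDING_ON_RATE
    kon_p = promoter_on_rate if promoter_on_rate is not None else PROMOTER_ON_RATE

    if architecture == "none":
        b = _Builder(["X", "Yf", "Yc"])
        b.add(p.c0 * omega, [], {}, {"Yf": +1}, delay=p.tau1)
        b.add(kon / omega, ["X", "Yf"], {"X": -1, "Yf": -1, "Yc": +1})
        b.add(kon * p.kc, ["Yc"], {"X": +1, "Yf": +1, "Yc": -1})
        b.add(p.deg_a, ["Yf"], {"Yf": -1})
        b.add(p.r_ikk, ["Yf"], {"Yf": -1}, k_dep=True)
        b.add(p.rho * p.r_ikk, ["Yc"], {"Yc": -1, "X": +1}, k_dep=True)
        eff = p.with_(constitutive_only=True, c1=0.0, eps=0.0)
        ya, _ = basal_state(eff, 0.0)
        return b.build(
            architecture, omega,
            _nfkb_init(eff, ya, 0.0, omega, n_nfkb_total, b.species), "X", eff,
            mean_state=_nfkb_mean_state(eff, ya, 0.0, omega, b.species),
        )

    species = ["X", "Yf", "Yc", "Ga_free", "Ga_bound"]
    dual = architecture == "dual"
    if dual:
        species += ["Zf", "Zc", "Ge_free", "Ge_bound"]
    b = _Builder(species)
    _add_ikb_loop(b, p, omega, gene="a", c0=p.c0, deg=p.deg_a, tau=p.tau1, scale=1.0,
                  yf="Yf", yc="Yc", kon=kon, kon_p=kon_p)
    if dual:
        _add_ikb_loop(b, p, omega, gene="e", c0=p.c0_e, deg=p.deg_e,
                      tau=p.tau1 + p.tau2, scale=p.eps, yf="Zf", yc="Zc",
                      kon=kon, kon_p=kon_p)
    eff = p if dual else p.with_(eps=0.0)
    ya, ye = basal_state(eff, 0.0)
    init = _nfkb_init(eff, ya, ye if dual else 0.0, omega, n_nfkb_total, species)
    return b.build(architecture, omega, init, "X", eff,
                   mean_state=_nfkb_mean_state(eff, ya, ye if dual else 0.0, omega, species))


def _add_ikb_loop(b: _Builder, p: ModelParams, omega: float, *, gene: str,
                  c0: float, deg: float, tau: float, scale: float, yf: str, yc: str,
                  kon: float = BINDING_ON_RATE, kon_p: float = PROMOTER_ON_RATE):
    gf, gb = f"G{gene}_free", f"G{gene}_bound"
    b.add(kon_p / omega, ["X", gf], {"X": -1, gf: -1, gb: +1})
    b.add(kon_p * p.kp, [gb], {"X": +1, gf: +1, gb: -1})
    b.add(scale * c0 * omega, [gf], {}, {yf: +1}, delay=tau)
    b.add(scale * p.c1 * omega, [gb], {}, {yf: +1}, delay=tau)
    b.add(kon / omega, ["X", yf], {"X": -1, yf: -1, yc: +1})
    b.add(kon * p.kc, [yc], {"X": +1, yf: +1, yc: -1})
    b.add(deg, [yf], {yf: -1})
    b.add(p.r_ikk, [yf], {yf: -1}, k_dep=True)
    b.add(p.rho * p.r_ikk, [yc], {yc: -1, "X": +1}, k_dep=True)


def _nfkb_init(p: ModelParams, ya: float, ye: float, omega: float,
               n_total: int, species: list[str]) -> np.ndarray:
    """Integer basal state satisfying exact NF-κB conservation."""
    x = solve_free_nfkb(ya, ye, p)
    f_bound = x / (p.kc + x)
    counts = dict.fromkeys(species, 0)
    yc = int(round(ya * f_bound * omega))
    counts["Yf"] = int(round(ya * (1 - f_bound) * omega))
    counts["Yc"] = yc
    zc = 0
    if "Zf" in counts:
        zc = int(round(ye * f_bound * omega))
        counts["Zf"] = int(round(ye * (1 - f_bound) * omega))
        counts["Zc"] = zc
    sequestered = yc + zc
    if sequestered > n_total:
        raise ValueError("basal state sequesters more NF-κB than available")
    counts["X"] = n_total - sequestered
    for g in ("Ga_free", "Ge_free", "G_free"):
        if g in counts:
            counts[g] = 1
    return np.array([counts[s] for s in species], dtype=np.int64)


def _nfkb_mean_state(p: ModelParams, ya: float, ye: float, omega: float,
                     species: list[str]) -> np.ndarray:
    """Continuous basal mean state with fractional promoter occupancy."""
    x = solve_free_nfkb(ya, ye, p)
    f_bound = x / (p.kc + x)
    pb = x / (p.kp + x)
    vals = dict.fromkeys(species, 0.0)
    vals["X"] = x * omega
    vals["Yf"] = ya * (1 - f_bound) * omega
    vals["Yc"] = ya * f_bound * omega
    if "Zf" in vals:
        vals["Zf"] = ye * (1 - f_bound) * omega
        vals["Zc"] = ye * f_bound * omega
    for gf, gb in (("Ga_free", "Ga_bound"), ("Ge_free", "Ge_bound")):
        if gf in vals:
            vals[gf], vals[gb] = 1.0 - pb, pb
    return np.array([vals[s] for s in species])


def _warm_start(network: ReactionNetwork, k_basal: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Stationary pre-stimulus pipeline for the delayed channels.

    Initiations before t = 0 at the basal mean propensity form a Poisson
    process; their completions land uniformly on (0, delay). Without this
    warm start the first `delay` minutes would see no synthesis at all,
    biasing the early response.
    """
    if network.mean_state is None:
        return np.empty(0), np.empty(0, dtype=np.int64)
    a = network.propensities(network.mean_state, k_basal)
    times, rxns = [], []
    for r in np.flatnonzero(network.delay > 0):
        n = rng.poisson(a[r] * network.delay[r])
        if n:
            times.append(rng.uniform(0.0, network.delay[r], n))
            rxns.append(np.full(n, r, dtype=np.int64))
    if not times:
        return np.empty(0), np.empty(0, dtype=np.int64)
    return np.concatenate(times), np.concatenate(rxns)


def _signal_arrays(signal: InputSignal, t_end: float):
    switches = [t for t in signal.switch_times() if 0.0 < t < t_end]
    ks = [signal.k(0.0)] + [signal.k(t + 1e-9) for t in switches]
    return np.asarray(switches, float), np.asarray(ks, float)


def simulate(
    network: ReactionNetwork,
    signal: InputSignal,
    t_end: float,
    seed: int,
    init=None,
    grid_dt: float = 1.0,
) -> StochTrajectory:
    """One exact delayed-SSA realization, sampled on a uniform grid.

    Samples use last-value interpolation of the jump process. The seed
    fully determines the event sequence.
    """
    init = network.init if init is None else np.asarray(init, dtype=np.int64)
    if np.any(init < 0):
        raise ValueError("initial counts must be nonnegative")
    grid = np.arange(0.0, t_end + 1e-9, grid_dt)
    switch_t, k_vals = _signal_arrays(signal, t_end)
    warm_t, warm_r = _warm_start(network, signal.k(0.0) if signal.t_on > 0 else signal.baseline,
                                 np.random.default_rng(seed))
    samples, n_events, status = run_ssa(
        init, network.rate, network.ri1, network.ri2, network.k_dep,
        network.delay, network.stoich_now, network.stoich_done,
        switch_t, k_vals, grid, seed, warm_t, warm_r,
    )
    if status == 1:
        raise RuntimeError("pending delayed-reaction queue overflow")
    return StochTrajectory(times=grid, counts=samples, species=list(network.species),
                           seed=seed, n_events=int(n_events))


def ensemble(
    network: ReactionNetwork,
    signal: InputSignal,
    t_end: float,
    n_runs: int,
    seed: int,
    grid_dt: float = 1.0,
    output: str | None = None,
    return_runs: bool = False,
):
    """Ensemble statistics of the output species over ``n_runs`` realizations.

    Run i uses seed ``seed + i`` (reproducible seed sequence). Returns an
    :class:`EnsembleSummary`; with ``return_runs=True`` also the
    (n_runs, n_times) output matrix.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be at least 2")
    name = output or network.output
    runs = []
    for i in range(n_runs):
        tr = simulate(network, signal, t_end, seed=seed + i, grid_dt=grid_dt)
        runs.append(tr.series(name))
    mat = np.array(runs, dtype=float)
    summ = EnsembleSummary(
        times=np.arange(0.0, t_end + 1e-9, grid_dt),
        mean=mat.mean(axis=0),
        sd=mat.std(axis=0, ddof=1),
        n_runs=n_runs,
    )
    if return_runs:
        return summ, mat
    return summ


def _first_peak_and_trough(times, mean, prominence=None):
    from scipy.signal import find_peaks

    prom = prominence if prominence is not None else 0.02 * float(np.max(mean))
    peaks, _ = find_peaks(mean, prominence=prom)
    if len(peaks) == 0:
        raise ValueError("mean trajectory has no identifiable first peak")
    ip = peaks[0]
    after = mean[ip:]
    troughs, _ = find_peaks(-after, prominence=prom)
    it = ip + (troughs[0] if len(troughs) else int(np.argmin(after)))
    return ip, it


def cv_peak_and_late(times, values, mode: str = "sd") -> tuple[float, float]:
    """Peak and late-phase coefficients of variation of a trajectory family.

    The peak CV is the across-family CV at the time of the mean
    trajectory's first peak; the late phase starts at the trough following
    that peak ("the nuclear NF-κB level following the trough after the
    first peak") and its CV is the time average of the per-time CV from
    there to the end.

    mode="sd": CV = sd/mean (intrinsic-noise convention);
    mode="halfrange": CV = (max - min)/(max + min) across the family
    (extrinsic parameter families).
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=0)
    ip, it = _first_peak_and_trough(times, mean)
    if mode == "sd":
        disp = values.std(axis=0, ddof=1)
        denom = mean
    elif mode == "halfrange":
        vmax, vmin = values.max(axis=0), values.min(axis=0)
        disp = vmax - vmin
        denom = vmax + vmin
    else:
        raise ValueError(f"unknown CV mode {mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(denom > 0, disp / denom, np.nan)
    cv_late = float(np.nanmean(cv[it:]))
    return float(cv[ip]), cv_late
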