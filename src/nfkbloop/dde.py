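"""Method-of-steps integration of the delayed feedback models.

The solver advances the coupled (y_a, y_e) system chunk by chunk with an
adaptive explicit Runge–Kutta scheme (``scipy.integrate.solve_ivp``,
dense output on). Chunk boundaries include every input switch time, its
delay images up to a configured depth, and are further subdivided so that
no chunk is longer than the smallest positive delay — delayed-state
lookups therefore always read already-completed segments (or the constant
pre-stimulus history).
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model import rhs_dual, solve_free_nfkb
from .params import InputSignal, ModelParams, no_feedback_variant

__all__ = ["IntegratorConfig", "Trajectory", "IntegrationError", "integrate", "basal_state"]

_VARIANTS = ("none", "single", "dual")


class IntegrationError(RuntimeError):
    """Raised when the step scheme fails; carries the last good time."""

    def __init__(self, message: str, t_last: float):
        super().__init__(f"{message} (last good time t = {t_last:g} min)")
        self.t_last = t_last


@dataclass(frozen=True)
class IntegratorConfig:
    """Tolerances and discontinuity handling for the DDE solver."""

    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_step: float = 5.0
    disc_depth: int = 2  # generations of delay images of input switches

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or self.abs_tol <= 0 or self.max_step <= 0:
            raise ValueError("tolerances and max_step must be positive")


@dataclass
class Trajectory:
    """Dense deterministic time course of the inhibitor levels.

    Stores the pre-stimulus history value and the per-chunk dense
    interpolants; any time in ``[t0 - max_delay, t_end]`` can be evaluated
    with accuracy consistent with the integrator order. Nuclear NF-κB is
    derived through the quasi-equilibrium algebra.
    """

    params: ModelParams
    signal: InputSignal
    history: np.ndarray  # constant (y_a, y_e) on t <= t0
    t0: float
    t_end: float
    segments: list = field(repr=False)  # list of (t_start, t_stop, OdeSolution)

    def _eval_state(self, t: float) -> np.ndarray:
        if t <= self.t0:
            return self.history
        starts = self._starts
        i = bisect.bisect_right(starts, t) - 1
        i = max(0, min(i, len(self.segments) - 1))
        sol = self.segments[i][2]
        return np.maximum(sol(min(t, self.segments[i][1])), 0.0)

    @property
    def _starts(self) -> list[float]:
        return [seg[0] for seg in self.segments]

    def state(self, t):
        """(y_a, y_e) at time(s) t, clamped to be nonnegative."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((t_arr.size, 2))
        for j, tj in enumerate(t_arr):
            out[j] = self._eval_state(tj)
        return out[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else out

    def y_a(self, t):
        s = self.state(t)
        return s[..., 0]

    def y_e(self, t):
        s = self.state(t)
        return s[..., 1]

    def x(self, t):
        """Nuclear NF-κB at time(s) t, nM."""
        s = np.atleast_2d(self.state(t))
        x = solve_free_nfkb(s[:, 0], s[:, 1], self.params)
        x = np.atleast_1d(x)
        return float(x[0]) if np.asarray(t).ndim == 0 else x

    def sample(self, times=None, dt: float = 0.2):
        """Sample the trajectory on a grid.

        Returns a dict of arrays with keys ``time_min``, ``y_alpha_nM``,
        ``y_eps_nM``, ``x_nM``.
        """
        if times is None:
            times = np.arange(self.t0, self.t_end + 1e-9, dt)
        times = np.asarray(times, dtype=float)
        states = np.atleast_2d(self.state(times))
        x = np.atleast_1d(solve_free_nfkb(states[:, 0], states[:, 1], self.params))
        return {
            "time_min": times,
            "y_alpha_nM": states[:, 0],
            "y_eps_nM": states[:, 1],
            "x_nM": x,
        }

    def to_frame(self, times=None, dt: float = 0.2):
        """Sampled trajectory as a pandas DataFrame (CSV-ready columns)."""
        import pandas as pd

        return pd.DataFrame(self.sample(times=times, dt=dt))


def basal_state(params: ModelParams, k: float = 0.0) -> np.ndarray:
    """Pre-stimulus steady state (y_a, y_e) at constant IKK activity ``k``.

    Reduces the two steady-state balances to a single scalar equation in
    nuclear NF-κB x: at steady state each total inhibitor level is
    synthesis/removal evaluated at x, and x must be consistent with those
    levels through the conservation law. Solved by bisection on x.
    """
    from scipy.optimize import brentq

    from .model import _removal_rate, _synthesis_alpha, _synthesis_eps

    p = params

    def levels(x: float):
        y_a = _synthesis_alpha(x, p) / _removal_rate(x, k, p.deg_a, p)
        if p.eps > 0:
            y_e = _synthesis_eps(x, p) / _removal_rate(x, k, p.deg_e, p)
        else:
            y_e = 0.0
        return y_a, y_e

    def mismatch(x: float) -> float:
        y_a, y_e = levels(x)
        return x - solve_free_nfkb(y_a, y_e, p)

    lo, hi = 1e-12, p.nf_tot
    if mismatch(lo) > 0:  # inhibitors cannot sequester NF-κB at all
        return np.array(levels(lo))
    x_star = brentq(mismatch, lo, hi, xtol=1e-12, rtol=1e-14)
    return np.array(levels(x_star))


def _effective_params(variant: str, params: ModelParams) -> ModelParams:
    if variant not in _VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}; expected one of {_VARIANTS}")
    if variant == "none":
        return no_feedback_variant(params)
    if variant == "single":
        return params.with_(eps=0.0)
    return params


def _breakpoints(signal: InputSignal, p: ModelParams, t0: float, t_end: float, depth: int):
    """Input switch times plus their delay images, restricted to (t0, t_end)."""
    base = [t for t in signal.switch_times() if t0 < t < t_end]
    pts = set(base)
    delays = [d for d in (p.tau1, p.tau1 + p.tau2) if d > 0]
    frontier = list(base) + [t0]
    for _ in range(depth):
        nxt = []
        for t in frontier:
            for d in delays:
                ti = t + d
                if t0 < ti < t_end and ti not in pts:
                    pts.add(ti)
                    nxt.append(ti)
        frontier = nxt
    return sorted(pts)


def integrate(
    variant: str,
    params: ModelParams,
    signal: InputSignal,
    t_end: float,
    history=None,
    t0: float = 0.0,
    config: IntegratorConfig | None = None,
) -> Trajectory:
    """Integrate a model variant under a piecewise-constant input.

    Parameters
    ----------
    variant : {"none", "single", "dual"}
        Feedback architecture. "none" disables induced synthesis, "single"
        removes the ε loop, "dual" uses the parameters as given.
    params : ModelParams
    signal : InputSignal
    t_end : float
        End time, min (> t0).
    history : array-like or None
        Constant (y_a, y_e) state on ``[t0 - max_delay, t0]``. Defaults to
        the basal steady state at ``K = signal.baseline`` — the resting-cell
        premise.
    config : IntegratorConfig, optional

    Returns
    -------
    Trajectory
        Dense solution with derived nuclear NF-κB.
    """
    cfg = config or IntegratorConfig()
    p = _effective_params(variant, params)
    if t_end <= t0:
        raise ValueError("t_end must exceed t0")
    if history is None:
        history = basal_state(p, k=signal.baseline)
    history = np.asarray(history, dtype=float)
    if history.shape != (2,) or np.any(history < 0):
        raise ValueError("history must be a nonnegative (y_a, y_e) pair")

    segments: list = []
    starts: list[float] = []

    def lookup(t: float) -> np.ndarray:
        if t <= t0:
            return history
        i = bisect.bisect_right(starts, t) - 1
        i = max(0, min(i, len(segments) - 1))
        return segments[i][2](min(t, segments[i][1]))

    tau_e = p.tau1 + p.tau2  # absolute IκBε synthesis delay

    def make_rhs(k_now: float):
        def rhs(t, y):
            state = np.maximum(y, 0.0)
            d1 = state if p.tau1 == 0 else np.maximum(lookup(t - p.tau1), 0.0)
            d2 = state if tau_e == 0 else np.maximum(lookup(t - tau_e), 0.0)
            return rhs_dual(state, d1, d2, k_now, p)

        return rhs

    # Chunk edges: breakpoints, subdivided below the smallest positive delay.
    edges = [t0] + _breakpoints(signal, p, t0, t_end, cfg.disc_depth) + [t_end]
    pos_delays = [d for d in (p.tau1, p.tau1 + p.tau2) if d > 0]
    max_chunk = min(pos_delays) if pos_delays else math.inf
    chunks: list[tuple[float, float]] = []
    for a, b in zip(edges[:-1], edges[1:]):
        n_sub = max(1, math.ceil((b - a) / max_chunk - 1e-12))
        sub = np.linspace(a, b, n_sub + 1)
        chunks.extend(zip(sub[:-1], sub[1:]))

    y = history.copy()
    for a, b in chunks:
        k_now = signal.k(0.5 * (a + b))
        sol = solve_ivp(
            make_rhs(k_now),
            (a, b),
            y,
            method="RK45",
            dense_output=True,
            rtol=cfg.rel_tol,
            atol=cfg.abs_tol,
            max_step=cfg.max_step,
        )
        if not sol.success:
            raise IntegrationError(sol.message, a)
        segments.append((a, b, sol.sol))
        starts.append(a)
        y = sol.y[:, -1]

    return Trajectory(
        params=p, signal=signal, history=history, t0=t0, t_end=t_end, segments=segments
    )
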