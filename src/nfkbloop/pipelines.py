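"""Headline analyses: damping optimization, duration encoding, noise scans.

These pipelines drive the deterministic and stochastic engines to
reproduce the module's four characteristic behaviors: (i) the second
feedback loop's delay/strength can be tuned to quench late oscillations;
(ii) the dual loop converts stimulus duration into response duration in a
graded way where the single loop quantizes; (iii) extrinsic parameter
scatter and intrinsic molecular noise shape response variability
differently across architectures; (iv) single-cell and population-average
damping metrics separate when trajectories desynchronize.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dde import IntegratorConfig, Trajectory, integrate
from .params import InputSignal, ModelParams, persistent, pulse
from .ssa import cv_peak_and_late
from .stability import measure_oscillations, summarize_series

__all__ = [
    "ScanResult",
    "DurationCurve",
    "damping_scan",
    "response_duration",
    "duration_response",
    "extrinsic_scan",
    "damping_metrics",
    "max_peak_trough_after",
]


@dataclass
class ScanResult:
    """Damping-metric surface over (tau2, eps) with its minimizer."""

    tau2_grid: np.ndarray
    eps_grid: np.ndarray
    metric: np.ndarray  # shape (len(eps_grid), len(tau2_grid)), nM; NaN = failed
    argmin: tuple[float, float]  # (tau2, eps) attaining the minimum

    def metric_at(self, tau2: float, eps: float) -> float:
        i = int(np.argmin(np.abs(self.eps_grid - eps)))
        j = int(np.argmin(np.abs(self.tau2_grid - tau2)))
        return float(self.metric[i, j])


@dataclass
class DurationCurve:
    """Response duration versus input duration at a fixed output threshold."""

    input_durations: np.ndarray  # min
    response_durations: np.ndarray  # min
    threshold: float  # nM


def damping_scan(
    params: ModelParams,
    k: float,
    tau2_grid,
    eps_grid,
    t_cut: float = 360.0,
    t_end: float = 600.0,
    config: IntegratorConfig | None = None,
) -> ScanResult:
    """Scan the persistence-of-oscillations metric over the ε-loop knobs.

    For each (tau2, eps) the dual model is integrated under persistent
    stimulation from basal history and scored by the largest nuclear
    NF-κB peak-trough difference occurring after ``t_cut`` (default 6 h).
    Failed integrations leave NaN and are excluded from the argmin.
    """
    tau2_grid = np.asarray(tau2_grid, dtype=float)
    eps_grid = np.asarray(eps_grid, dtype=float)
    metric = np.full((eps_grid.size, tau2_grid.size), np.nan)
    signal = persistent(k)
    for i, eps in enumerate(eps_grid):
        for j, tau2 in enumerate(tau2_grid):
            p = params.with_(eps=float(eps), tau2=float(tau2))
            try:
                traj = integrate("dual", p, signal, t_end, config=config)
                metric[i, j] = measure_oscillations(traj, t_cut=t_cut).max_peak_trough_after(t_cut)
            except RuntimeError:
                continue
    if np.all(np.isnan(metric)):
        raise RuntimeError("all damping-scan grid points failed to integrate")
    i, j = np.unravel_index(np.nanargmin(metric), metric.shape)
    return ScanResult(
        tau2_grid=tau2_grid,
        eps_grid=eps_grid,
        metric=metric,
        argmin=(float(tau2_grid[j]), float(eps_grid[i])),
    )


def response_duration(traj: Trajectory, threshold: float = 50.0, dt: float = 0.05) -> float:
    """Total time the nuclear NF-κB trajectory exceeds a threshold, min.

    Crossings are bracketed on a dense sample and refined by root
    finding on the dense interpolant, so the measure is insensitive to
    the sampling step.
    """
    from scipy.optimize import brentq

    t = np.arange(traj.t0, traj.t_end + 1e-9, dt)
    above = traj.x(t) > threshold
    if not np.any(above):
        return 0.0
    f = lambda s: traj.x(float(s)) - threshold
    total = 0.0
    edges = np.flatnonzero(np.diff(above.astype(int)))
    crossings = [brentq(f, t[i], t[i + 1], xtol=1e-6) for i in edges]
    bounds = ([traj.t0] if above[0] else []) + crossings + ([traj.t_end] if above[-1] else [])
    for lo, hi in zip(bounds[0::2], bounds[1::2]):
        total += hi - lo
    return total


def duration_response(
    variant: str,
    params: ModelParams,
    k: float,
    pulse_durations,
    threshold: float = 50.0,
    t_end: float = 480.0,
    config: IntegratorConfig | None = None,
) -> DurationCurve:
    """Temporal dose-response: output duration for each input pulse length.

    Pulses start at t = 0 from basal history; the response duration is
    the total time nuclear NF-κB spends above ``threshold`` (50 nM by
    default, the level used for the duration-encoding comparison).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    durations = np.asarray(pulse_durations, dtype=float)
    out = np.empty_like(durations)
    for i, d in enumerate(durations):
        sig = pulse(k, float(d)) if math.isfinite(d) else persistent(k)
        traj = integrate(variant, params, sig, t_end, config=config)
        out[i] = response_duration(traj, threshold=threshold)
    return DurationCurve(input_durations=durations, response_durations=out, threshold=threshold)


def extrinsic_scan(
    params: ModelParams,
    vary: str,
    base_values,
    k_nominal: float = 1.0,
    fraction: float = 0.25,
    n_family: int = 3,
    variant: str = "dual",
    t_end: float = 600.0,
    grid_dt: float = 1.0,
    cv_mode: str = "halfrange",
    config: IntegratorConfig | None = None,
):
    """Response variability from cell-to-cell parameter scatter.

    A deterministic family of ``n_family`` trajectories is generated with
    the varied quantity (total NF-κB or the input level K) evenly spaced
    over ±``fraction`` (default ±25%, the measurement-error scale of the
    protein quantitation) around its nominal value, for each base value
    of the other axis. Returns a list of (cv_peak, cv_late) pairs.

    vary="nf_tot": base_values are input levels K;
    vary="K": base_values are total NF-κB levels, input amplitude scatter
    around ``k_nominal``.
    """
    if vary not in ("nf_tot", "K"):
        raise ValueError("vary must be 'nf_tot' or 'K'")
    if fraction < 0:
        raise ValueError("fraction must be nonnegative")
    if n_family < 3:
        raise ValueError("n_family must be at least 3")
    factors = np.linspace(1.0 - fraction, 1.0 + fraction, n_family)
    times = np.arange(0.0, t_end + 1e-9, grid_dt)
    results = []
    for base in np.atleast_1d(base_values):
        fam = []
        for f in factors:
            if vary == "nf_tot":
                p, kk = params.with_(nf_tot=float(params.nf_tot * f)), float(base)
            else:
                p, kk = params.with_(nf_tot=float(base)), float(k_nominal * f)
            traj = integrate(variant, p, persistent(kk), t_end, config=config)
            fam.append(traj.x(times))
        results.append(cv_peak_and_late(times, np.array(fam), mode=cv_mode))
    return results


def max_peak_trough_after(times, values, t_after: float, prominence: float) -> float:
    """Largest peak-minus-following-trough of a series after ``t_after``."""
    return summarize_series(times, values, prominence).max_peak_trough_after(t_after)


def damping_metrics(times, values, t_after: float = 300.0, prominence: float | None = None,
                    smooth: int = 9):
    """Single-cell versus population measures of late oscillation amplitude.

    ``a_single`` scores each trajectory's own maximum late peak-trough
    difference and averages over the family; ``a_population`` scores the
    pointwise-mean trajectory. Desynchronized oscillators keep a_single
    large while a_population collapses, so a_population <= a_single up to
    sampling tolerance.

    Stochastic trajectories are moving-average smoothed over ``smooth``
    grid points before peak detection, and the default prominence is 5% of
    the family's range; otherwise shot noise inserts spurious troughs next
    to every peak and truncates the measured single-cell amplitudes.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need at least 2 trajectories on a common grid")
    if smooth > 1:
        kernel = np.ones(smooth)
        norm = np.convolve(np.ones(values.shape[1]), kernel, mode="same")
        values = np.apply_along_axis(
            lambda v: np.convolve(v, kernel, mode="same") / norm, 1, values
        )
    if prominence is None:
        prominence = 0.05 * float(np.max(values) - np.min(values))
    singles = [max_peak_trough_after(times, v, t_after, prominence) for v in values]
    a_single = float(np.mean(singles))
    a_population = max_peak_trough_after(times, values.mean(axis=0), t_after, prominence)
    return a_single, float(a_population)
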