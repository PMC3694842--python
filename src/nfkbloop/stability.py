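"""Fixed points, Lambert-W eigenvalues, and numerical oscillation metrics.

For the single-feedback model under constant input K the dynamics close to
a scalar DDE ``dy/dt = F(y, y_tau)``. Linearizing about the fixed point
``y*`` gives ``d(δy)/dt = -a δy - b δy_tau`` with instantaneous coefficient
``a`` and delayed coefficient ``b``; the dominant eigenvalue is

    λ = -a + W(-b τ exp(a τ)) / τ

with W the Lambert function (W e^W = z). The imaginary part of λ sets the
oscillation frequency (period 2π / Im λ) and the negative real part the
decay rate. In the stimulated regime (induced synthesis and degradation
dominating basal ones, total NF-κB well above the binding constants) the
coefficients take the simple closed forms used here by default; the full
linearization of the unreduced right-hand side is available for
cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.signal import find_peaks
from scipy.special import lambertw

from .model import rhs_single
from .params import ModelParams

__all__ = [
    "LinearizationResult",
    "OscillationSummary",
    "fixed_point",
    "fixed_point_large_k",
    "linear_coefficients",
    "dominant_eigenvalue",
    "period_sensitivity",
    "measure_oscillations",
    "summarize_series",
]


@dataclass(frozen=True)
class LinearizationResult:
    """Dominant eigenvalue of the linearized single-loop model."""

    y_star: float  # fixed point of total IκBα, nM
    eigenvalue: complex  # 1/min
    a: float  # instantaneous linear coefficient, 1/min
    b: float  # delayed linear coefficient, 1/min
    tau: float  # delay used, min

    @property
    def period(self) -> float:
        """Oscillation period 2π/Im λ, min (nan in the overdamped regime)."""
        im = self.eigenvalue.imag
        return 2.0 * math.pi / im if im > 0 else math.nan

    @property
    def decay_rate(self) -> float:
        """Decay rate -Re λ, 1/min (negative if the fixed point is unstable)."""
        return -self.eigenvalue.real

    @property
    def oscillatory(self) -> bool:
        return self.eigenvalue.imag > 0

    def residual(self) -> float:
        """|λ + a + b e^{-λτ}| — characteristic-equation residual."""
        lam = self.eigenvalue
        return abs(lam + self.a + self.b * np.exp(-lam * self.tau))


def fixed_point(params: ModelParams, k: float) -> float:
    """Stationary total IκBα of the single-loop model at constant input.

    Root of the closed right-hand side with the delayed argument equal to
    the instantaneous one; bracketed and solved by Brent's method.
    """
    if k < 0:
        raise ValueError("K must be nonnegative")
    p = params.with_(eps=0.0)

    def f(y: float) -> float:
        return rhs_single(y, y, k, p)

    hi = 2.0 * (p.c0 + p.c1) / max(p.deg_a, 1e-12) + p.nf_tot
    lo = 0.0
    f_lo, f_hi = f(lo), f(hi)
    while f_hi > 0:
        hi *= 2
        f_hi = f(hi)
        if hi > 1e12:
            raise RuntimeError(f"fixed-point bracketing failed on [0, {hi:g}] nM")
    if f_lo < 0:
        raise RuntimeError("no positive synthesis at y = 0; cannot bracket fixed point")
    return brentq(f, lo, hi, xtol=1e-12, rtol=1e-15)


def fixed_point_large_k(params: ModelParams, k: float) -> float:
    """Explicit stationary IκBα in the strongly stimulated regime.

    Neglecting basal synthesis and constitutive degradation and taking
    total NF-κB large against the binding constants (free NF-κB
    x ≈ nf_tot - y, complexed fraction ≈ 1), the balance

        c1 (nf_tot - y) / (kp + nf_tot - y) = rho r_ikk K y

    is a quadratic in u = nf_tot - y with an explicit positive root.
    """
    p = params
    g = p.rho * p.r_ikk * k
    if g <= 0:
        raise ValueError("requires K > 0 and rho * r_ikk > 0")
    # g u^2 + (c1 + g (kp - nf)) u - g nf kp = 0
    bq = p.c1 + g * (p.kp - p.nf_tot)
    u = (-bq + math.sqrt(bq * bq + 4.0 * g * g * p.nf_tot * p.kp)) / (2.0 * g)
    return p.nf_tot - u


def linear_coefficients(
    params: ModelParams, k: float, form: str = "simplified"
) -> tuple[float, float, float]:
    """Coefficients (a, b) of the linearized scalar DDE and the fixed point.

    form="simplified": the stimulated-regime closed forms,
        a = rho r_ikk K,  b = c1 kp / (kp + nf_tot - y*)^2,
    with y* from :func:`fixed_point_large_k`.
    form="full": central finite differences of the unreduced right-hand
    side about the numeric fixed point (cross-check path).
    """
    p = params
    if form == "simplified":
        y_star = fixed_point_large_k(p, k)
        a = p.rho * p.r_ikk * k
        x_star = p.nf_tot - y_star
        b = p.c1 * p.kp / (p.kp + x_star) ** 2
        return a, b, y_star
    if form == "full":
        y_star = fixed_point(p, k)
        h = max(1e-6 * y_star, 1e-8)
        a = -(rhs_single(y_star + h, y_star, k, p) - rhs_single(y_star - h, y_star, k, p)) / (2 * h)
        b = -(rhs_single(y_star, y_star + h, k, p) - rhs_single(y_star, y_star - h, k, p)) / (2 * h)
        return a, b, y_star
    raise ValueError(f"unknown linearization form {form!r}")


def dominant_eigenvalue(
    params: ModelParams, k: float, form: str = "simplified"
) -> LinearizationResult:
    """Rightmost eigenvalue of the linearized single-loop model.

    Uses the principal branch of the Lambert function, which yields the
    rightmost root for the real arguments arising here; below the branch
    point -1/e it gives the dominant complex-conjugate pair, of which the
    Im > 0 representative is returned.
    """
    a, b, y_star = linear_coefficients(params, k, form=form)
    tau = params.tau1
    if tau == 0:
        lam = complex(-(a + b), 0.0)
    elif b == 0:
        lam = complex(-a, 0.0)
    else:
        arg = complex(-b * tau * math.exp(a * tau), 0.0)
        w = lambertw(arg, 0)
        if np.isnan(w.real):  # numerical singularity exactly at the -1/e branch point
            w = lambertw(arg * (1.0 - 1e-9), 0)
        lam = -a + w / tau
        if lam.imag < 0:
            lam = lam.conjugate()
    res = LinearizationResult(y_star=y_star, eigenvalue=lam, a=a, b=b, tau=tau)
    if tau > 0 and res.residual() > 1e-9 * max(1.0, abs(lam)):
        raise RuntimeError(f"characteristic equation residual {res.residual():g} too large")
    return res


def period_sensitivity(params: ModelParams, k_grid, tau_grid, form: str = "simplified"):
    """Analytic period and decay over a (tau, K) product grid.

    Returns a pandas DataFrame with columns
    ``tau_min, k, period_min, decay_per_min``.
    """
    import pandas as pd

    rows = []
    for tau in np.atleast_1d(tau_grid):
        p_tau = params.with_(tau1=float(tau))
        for k in np.atleast_1d(k_grid):
            r = dominant_eigenvalue(p_tau, float(k), form=form)
            rows.append(
                {
                    "tau_min": float(tau),
                    "k": float(k),
                    "period_min": r.period,
                    "decay_per_min": r.decay_rate,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class OscillationSummary:
    """Peak/trough census of a (possibly damped) oscillatory time course."""

    peak_times: np.ndarray
    peak_values: np.ndarray
    trough_times: np.ndarray
    trough_values: np.ndarray
    period: float  # mean inter-peak spacing, min; nan if < 2 peaks
    decay: float  # 1/min from log-linear fit of peak-trough amplitudes; nan if < 2

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times)

    def amplitudes(self):
        """Peak minus following-trough amplitude for each peak."""
        amps = []
        for tp, vp in zip(self.peak_times, self.peak_values):
            later = self.trough_values[self.trough_times > tp]
            if later.size:
                amps.append(vp - later[0])
        return np.asarray(amps)

    def max_peak_trough_after(self, t_cut: float) -> float:
        """Largest (peak - following trough) with peak time >= t_cut.

        The persistence-of-oscillations metric; 0 if no peak after t_cut.
        """
        best = 0.0
        for tp, vp in zip(self.peak_times, self.peak_values):
            if tp < t_cut:
                continue
            later = self.trough_values[self.trough_times > tp]
            if later.size:
                best = max(best, vp - later[0])
        return best


def summarize_series(times, values, prominence: float) -> OscillationSummary:
    """Detect peaks/troughs on a sampled series and estimate period and decay."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ip, _ = find_peaks(values, prominence=prominence)
    it, _ = find_peaks(-values, prominence=prominence)
    # terminal trough: the series end acts as the trough after the last peak
    trough_idx = np.sort(np.append(it, len(values) - 1)) if ip.size else it
    peak_times, peak_values = times[ip], values[ip]
    trough_times, trough_values = times[trough_idx], values[trough_idx]

    period = float(np.mean(np.diff(peak_times))) if len(ip) >= 2 else math.nan

    decay = math.nan
    amps, amp_t = [], []
    for tp, vp in zip(peak_times, peak_values):
        later = trough_values[trough_times > tp]
        if later.size:
            amp = vp - later[0]
            if amp > 0:
                amps.append(amp)
                amp_t.append(tp)
    if len(amps) >= 2:
        slope = np.polyfit(amp_t, np.log(amps), 1)[0]
        decay = -float(slope)

    return OscillationSummary(
        peak_times=peak_times,
        peak_values=peak_values,
        trough_times=trough_times,
        trough_values=trough_values,
        period=period,
        decay=decay,
    )


def measure_oscillations(traj, t_cut: float = 360.0, prominence: float | None = None, dt: float = 0.1):
    """Oscillation summary of a trajectory's nuclear NF-κB course.

    Peak detection uses a minimum prominence of 1% of total NF-κB by
    default, which rejects integrator ripple. ``t_cut`` is retained by the
    caller through :meth:`OscillationSummary.max_peak_trough_after`.
    """
    if prominence is None:
        prominence = 0.01 * traj.params.nf_tot
    s = traj.sample(dt=dt)
    if traj.t_end < t_cut:
        raise ValueError("trajectory must span beyond t_cut")
    return summarize_series(s["time_min"], s["x_nM"], prominence)
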