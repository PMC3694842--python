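"""Surrogate experimental observables and calibration procedures.

Emulates the quantitated readouts the module's parameters were derived
from — mRNA induction time courses (RNase-protection-style band
intensities), sampled nuclear NF-κB trajectories, and basal/peak protein
abundances with multiplicative measurement error — together with the
estimation procedures applied to them: half-maximal induction delay
estimation and anchor-based parameter calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dde import integrate
from .params import InputSignal, ModelParams, persistent
from .pipelines import response_duration
from .stability import measure_oscillations

__all__ = [
    "TimeCourseSample",
    "gen_mrna_course",
    "gen_nfkb_course",
    "gen_protein_abundances",
    "estimate_half_max_delay",
    "peak_ratio",
    "Anchor",
    "ANCHOR_EVALUATORS",
    "CalibrationResult",
    "calibrate_parameters",
]


@dataclass
class TimeCourseSample:
    """A sampled, possibly noisy experimental time course."""

    times: np.ndarray  # min, strictly increasing
    values: np.ndarray  # arbitrary units, >= 0
    noise_model: str
    seed: int | None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def _apply_noise(values, noise_cv: float, rng, model: str):
    if noise_cv == 0:
        return values.copy()
    if model == "lognormal":
        # multiplicative with unit mean and the requested CV
        sigma = math.sqrt(math.log1p(noise_cv**2))
        return values * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=values.shape)
    if model == "gaussian":
        return values + rng.normal(0.0, noise_cv * values, size=values.shape)
    raise ValueError(f"unknown noise model {model!r}")


def gen_mrna_course(
    true_delay: float,
    rise_sharpness: float = 0.15,
    basal: float = 5.0,
    peak: float = 100.0,
    sample_times=None,
    noise_cv: float = 0.0,
    seed: int | None = None,
    noise_model: str = "lognormal",
) -> TimeCourseSample:
    """Sigmoidal mRNA induction crossing half-maximum at ``true_delay``.

    A logistic rise from ``basal`` to ``peak`` (band-intensity units)
    sampled at ``sample_times`` (default every 15 min over 3 h), with
    multiplicative lognormal noise of the given CV — the shape of a
    quantitated induction time course used to read off a synthesis delay.
    """
    if basal >= peak:
        raise ValueError("basal must be below peak")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    if sample_times is None:
        sample_times = np.arange(0.0, 181.0, 15.0)
    t = np.asarray(sample_times, dtype=float)
    clean = basal + (peak - basal) / (1.0 + np.exp(-rise_sharpness * (t - true_delay)))
    rng = np.random.default_rng(seed)
    noisy = np.maximum(_apply_noise(clean, noise_cv, rng, noise_model), 0.0)
    return TimeCourseSample(times=t, values=noisy, noise_model=noise_model, seed=seed)


def gen_nfkb_course(
    params: ModelParams,
    signal: InputSignal,
    sample_times,
    noise_cv: float = 0.1,
    seed: int | None = None,
    variant: str = "dual",
) -> TimeCourseSample:
    """Sampled noisy nuclear NF-κB trajectory (gel-shift-like readout)."""
    t_end = float(np.max(sample_times)) + 1.0
    traj = integrate(variant, params, signal, t_end)
    clean = np.atleast_1d(traj.x(np.asarray(sample_times, dtype=float)))
    rng = np.random.default_rng(seed)
    vals = np.maximum(_apply_noise(clean, noise_cv, rng, "lognormal"), 0.0)
    return TimeCourseSample(times=np.asarray(sample_times, float), values=vals,
                            noise_model="lognormal", seed=seed)


def gen_protein_abundances(
    basal: float,
    fold_induction: float,
    n_replicates: int = 5,
    noise_cv: float = 0.25,
    seed: int | None = None,
):
    """Replicate basal/peak protein abundances with multiplicative error.

    The default 25% CV reflects the stated uncertainty of absolute
    protein quantitation against recombinant standards. Returns
    (basal_samples, peak_samples).
    """
    rng = np.random.default_rng(seed)
    basal_arr = np.full(n_replicates, float(basal))
    peak_arr = basal_arr * fold_induction
    return (
        _apply_noise(basal_arr, noise_cv, rng, "lognormal"),
        _apply_noise(peak_arr, noise_cv, rng, "lognormal"),
    )


def estimate_half_max_delay(sample: TimeCourseSample) -> float:
    """Synthesis delay as the half-maximal induction time.

    The course is normalized so its maximum reads 100%; the basal level is
    the first point. Returns the first time the linearly interpolated
    curve crosses the midpoint of the basal-to-peak range.
    """
    t, v = sample.times, sample.values
    basal = v[0]
    peak = float(np.max(v))
    if peak <= basal:
        raise ValueError("course has no induction above the basal point")
    level = basal + 0.5 * (peak - basal)
    above = v >= level
    idx = np.flatnonzero(above[1:])  # first crossing after the basal point
    if idx.size == 0:
        raise ValueError("course never crosses the half-maximal level")
    i = idx[0] + 1
    if v[i] == v[i - 1]:
        return float(t[i])
    frac = (level - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def peak_ratio(
    params: ModelParams,
    k: float = 1.0,
    t_end: float = 600.0,
    eps: float | None = 1.0,
) -> float:
    """Ratio of peak total IκBα to peak total IκBε under persistent input.

    With ``eps`` forced to 1 the two synthesis pipelines are equally
    strong and the ratio isolates the kinetic asymmetry between the
    isoforms; scanning ``eps`` and inverting this map is how a measured
    protein ratio is converted into a feedback-strength estimate.
    """
    p = params if eps is None else params.with_(eps=float(eps))
    if p.eps <= 0:
        raise ValueError("peak_ratio requires an active ε loop (eps > 0)")
    traj = integrate("dual", p, persistent(k), t_end)
    s = traj.sample(dt=0.25)
    return float(s["y_alpha_nM"].max() / s["y_eps_nM"].max())


@dataclass(frozen=True)
class Anchor:
    """A named target observable with tolerance used in calibration."""

    name: str
    target: float
    tol: float  # relative tolerance defining success


def _eval_period(p: ModelParams, k: float) -> float:
    traj = integrate("single", p, persistent(k), 600.0)
    return measure_oscillations(traj, t_cut=360.0).period


def _eval_peak_x(p: ModelParams, k: float) -> float:
    traj = integrate("single", p, persistent(k), 300.0)
    return float(np.max(traj.x(np.arange(0.0, 300.0, 0.25))))


def _eval_peak_ratio(p: ModelParams, k: float) -> float:
    return peak_ratio(p, k=k)


def _eval_pulse15(p: ModelParams, k: float) -> float:
    from .params import pulse

    traj = integrate("dual", p, pulse(k, 15.0), 480.0)
    return response_duration(traj, threshold=50.0)


#: Observables calibration can anchor on, each a map (params, K) -> value.
ANCHOR_EVALUATORS = {
    "single_period": _eval_period,
    "single_peak_x": _eval_peak_x,
    "peak_ratio_eps1": _eval_peak_ratio,
    "pulse15_duration": _eval_pulse15,
}


@dataclass
class CalibrationResult:
    params: ModelParams
    residuals: dict[str, float]  # relative deviation per anchor
    achieved: dict[str, float]
    n_evaluations: int
    objective_trace: list[float] = field(repr=False, default_factory=list)

    @property
    def success(self) -> bool:
        return all(abs(r) <= 1.0 for r in self.residuals.values())

    def worst_anchor(self) -> str:
        return max(self.residuals, key=lambda n: abs(self.residuals[n]))


def calibrate_parameters(
    anchors: list[Anchor],
    free: dict[str, tuple[float, float]],
    start: ModelParams,
    k: float = 1.0,
    max_evaluations: int = 400,
) -> CalibrationResult:
    """Fit free parameters so model observables match anchor targets.

    Minimizes the sum of squared tolerance-normalized residuals
    ((value/target - 1)/tol)^2 with a bounded derivative-free local
    search (Powell) from ``start``. Deterministic given the start and
    bounds. Raises no exception on failure; inspect ``success`` and the
    worst anchor of the returned report.
    """
    if not anchors:
        raise ValueError("need at least one anchor")
    for a in anchors:
        if a.name not in ANCHOR_EVALUATORS:
            raise ValueError(f"unknown anchor {a.name!r}; known: {sorted(ANCHOR_EVALUATORS)}")
    names = list(free)
    trace: list[float] = []
    n_eval = 0

    def residuals(p: ModelParams) -> dict[str, float]:
        out = {}
        for a in anchors:
            try:
                v = ANCHOR_EVALUATORS[a.name](p, k)
            except Exception:
                v = math.nan
            out[a.name] = (v / a.target - 1.0) / a.tol if math.isfinite(v) else 1e3
        return out

    if not names:
        res = residuals(start)
        return CalibrationResult(
            params=start,
            residuals=res,
            achieved={a.name: (1 + res[a.name] * a.tol) * a.target for a in anchors},
            n_evaluations=1,
        )

    from scipy.optimize import minimize

    def objective(vec) -> float:
        nonlocal n_eval
        n_eval += 1
        p = start.with_(**{n: float(v) for n, v in zip(names, vec)})
        val = sum(r * r for r in residuals(p).values())
        trace.append(min(val, trace[-1]) if trace else val)
        return val

    x0 = [getattr(start, n) for n in names]
    bounds = [free[n] for n in names]
    sol = minimize(objective, x0, method="Powell", bounds=bounds,
                   options={"maxfev": max_evaluations, "xtol": 1e-3, "ftol": 1e-4})
    fitted = start.with_(**{n: float(v) for n, v in zip(names, sol.x)})
    res = residuals(fitted)
    achieved = {a.name: (1 + res[a.name] * a.tol) * a.target for a in anchors}
    return CalibrationResult(params=fitted, residuals=res, achieved=achieved,
                             n_evaluations=n_eval, objective_trace=trace)
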