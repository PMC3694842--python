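"""Model parameters and input signals for the IκB–NF-κB delayed feedback module.

Concentrations are in nM, time in minutes, and the IKK activity ``K`` is
dimensionless throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace


@dataclass(frozen=True)
class ModelParams:
    """Kinetic constants of the reduced delayed-feedback models.

    The single-feedback model tracks total IκBα (free plus NF-κB-bound);
    the dual-feedback model adds total IκBε. Nuclear NF-κB is a derived
    quantity obtained from the quasi-equilibrium binding algebra.

    Attributes
    ----------
    nf_tot : float
        Total (conserved) NF-κB concentration, nM.
    c0 : float
        Constitutive IκBα synthesis rate from the unbound promoter, nM/min.
    c1 : float
        Induced IκBα synthesis rate from the NF-κB-bound promoter, nM/min.
    deg_a : float
        Constitutive degradation rate of free IκBα, 1/min.
    r_ikk : float
        IKK-mediated degradation rate coefficient of free IκB per unit K, 1/min.
    rho : float
        Ratio of IKK-mediated degradation of NF-κB-bound IκB to free IκB
        (order 1), dimensionless.
    kp : float
        Promoter-binding dissociation constant of NF-κB, nM.
    kc : float
        IκB–NF-κB complex dissociation constant, nM.
    tau1 : float
        IκBα synthesis delay (transcription/translation/transport), min.
    tau2 : float
        Additional IκBε synthesis delay on top of the IκBα pipeline, min.
        The absolute ε delay is ``tau1 + tau2``: IκBε induction engages
        later than IκBα's, and this increment is what the delay scan of the
        damping analysis varies.
    eps : float
        IκBε feedback-strength scaling factor; scales both constitutive and
        induced IκBε synthesis. ``eps = 0`` removes the second loop exactly.
    c0_e : float
        Constitutive IκBε synthesis rate, nM/min.
    deg_e : float
        Constitutive degradation rate of free IκBε, 1/min.
    constitutive_only : bool
        If True, IκBα synthesis ignores the promoter and proceeds at the
        constant rate ``c0`` (the no-feedback variant).
    """

    nf_tot: float
    c0: float
    c1: float
    deg_a: float
    r_ikk: float
    rho: float
    kp: float
    kc: float
    tau1: float
    tau2: float
    eps: float = 0.0
    c0_e: float = 0.0
    deg_e: float = 0.0
    constitutive_only: bool = False

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "constitutive_only":
                continue
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and nonnegative, got {v}")
        for name in ("nf_tot", "kp", "kc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_(self, **kw) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


def no_feedback_variant(params: ModelParams, c0: float | None = None) -> ModelParams:
    """Disable induced synthesis, yielding a constitutively produced inhibitor.

    Sets ``c1 = 0`` and removes the promoter dependence of synthesis.
    Optionally overrides the constitutive rate ``c0`` (raising it speeds up
    post-pulse attenuation at the cost of response amplitude).
    """
    kw = dict(c1=0.0, constitutive_only=True)
    if c0 is not None:
        kw["c0"] = c0
    return params.with_(**kw)


@dataclass(frozen=True)
class InputSignal:
    """Piecewise-constant IKK activity K(t).

    ``K(t) = baseline`` outside ``[t_on, t_on + duration)`` and ``amplitude``
    inside. ``duration`` may be infinite (persistent stimulation).
    """

    amplitude: float
    t_on: float = 0.0
    duration: float = math.inf
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.baseline < 0:
            raise ValueError("IKK activity must be nonnegative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def t_off(self) -> float:
        return self.t_on + self.duration

    def k(self, t: float) -> float:
        """IKK activity at time ``t`` (scalar)."""
        if self.t_on <= t < self.t_off:
            return self.amplitude
        return self.baseline

    def switch_times(self) -> list[float]:
        """Finite discontinuity times of K(t), sorted."""
        out = [self.t_on]
        if math.isfinite(self.t_off):
            out.append(self.t_off)
        return out


def persistent(amplitude: float, t_on: float = 0.0) -> InputSignal:
    """Persistent stimulation switched on at ``t_on``."""
    return InputSignal(amplitude=amplitude, t_on=t_on)


def pulse(amplitude: float, duration: float, t_on: float = 0.0) -> InputSignal:
    """A single square pulse of IKK activity."""
    return InputSignal(amplitude=amplitude, t_on=t_on, duration=duration)
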