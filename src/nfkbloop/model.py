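"""Quasi-equilibrium algebra and delay-differential right-hand sides.

The reduced models follow from the full mass-action system by three
assumptions: (i) total NF-κB is conserved; (ii) promoter-bound NF-κB is
negligible against the total; (iii) promoter binding and IκB–NF-κB binding
are fast and stay at quasi-equilibrium. The slow variables are then the
total inhibitor levels ``y_a`` (IκBα, free + complexed) and ``y_e`` (IκBε),
and nuclear NF-κB ``x`` is an algebraic function of them.
"""

from __future__ import annotations

import math

import numpy as np

from .params import ModelParams

__all__ = [
    "promoter_occupancy",
    "solve_free_nfkb",
    "free_nfkb_fixed_point_iteration",
    "complex_fractions",
    "rhs_single",
    "rhs_dual",
]


def promoter_occupancy(x, kp: float):
    """Probabilities for an IκB promoter to be free of / bound by NF-κB.

    With fast promoter binding at dissociation constant ``kp`` the bound
    probability is the hyperbolic saturation ``x / (kp + x)``.

    Parameters
    ----------
    x : float or ndarray
        Nuclear NF-κB concentration, nM (>= 0).
    kp : float
        Promoter dissociation constant, nM (> 0).

    Returns
    -------
    (p_free, p_bound)
        Occupancy probabilities summing to one.
    """
    if kp <= 0:
        raise ValueError("kp must be positive")
    if np.any(np.asarray(x) < 0):
        raise ValueError("nuclear NF-κB concentration must be nonnegative")
    p_bound = x / (kp + x)
    return 1.0 - p_bound, p_bound


def solve_free_nfkb(y_a, y_e, params: ModelParams):
    """Nuclear (free) NF-κB given total IκBα and IκBε levels.

    NF-κB is conserved between the free pool and the complexes with each
    isoform (promoter-bound NF-κB is neglected). With both complexes at
    quasi-equilibrium with the same dissociation constant ``kc``, the free
    level solves

        x^2 + (kc + y - nf_tot) x - nf_tot * kc = 0,   y = y_a + y_e,

    whose unique nonnegative root is returned in a cancellation-free form.
    Accepts scalars or arrays.
    """
    y_a = np.asarray(y_a, dtype=float)
    y_e = np.asarray(y_e, dtype=float)
    if np.any(y_a < 0) or np.any(y_e < 0):
        raise ValueError("inhibitor levels must be nonnegative")
    nf, kc = params.nf_tot, params.kc
    b = kc + y_a + y_e - nf
    x = 2.0 * nf * kc / (b + np.hypot(b, 2.0 * math.sqrt(nf * kc)))
    if x.ndim == 0:
        return float(x)
    return x


def free_nfkb_fixed_point_iteration(
    y_a: float, y_e: float, params: ModelParams, tol: float = 1e-14, max_iter: int = 100_000
) -> float:
    """Free NF-κB by damped fixed-point iteration on the binding relations.

    Independent of the closed-form root: iterates
    ``x <- nf_tot - (y_a + y_e) * x / (kc + x)`` with under-relaxation.
    Used as a brute-force oracle for :func:`solve_free_nfkb`.
    """
    nf, kc = params.nf_tot, params.kc
    y = y_a + y_e
    x = nf / 2.0
    for _ in range(max_iter):
        x_new = max(nf - y * x / (kc + x), 0.0)
        # damping adapted to the local map slope keeps the iteration stable
        slope = y * kc / (kc + x) ** 2
        alpha = 1.0 / (1.0 + slope)
        x_next = (1 - alpha) * x + alpha * x_new
        if abs(x_next - x) < tol * max(1.0, x):
            return x_next
        x = x_next
    return x


def complex_fractions(x, params: ModelParams):
    """Free and NF-κB-bound fractions of a total inhibitor pool.

    At binding quasi-equilibrium a fraction ``kc / (kc + x)`` of the total
    inhibitor is free and ``x / (kc + x)`` is complexed with NF-κB; the same
    split applies to both isoforms since they share ``kc``.
    """
    f_bound = x / (params.kc + x)
    return 1.0 - f_bound, f_bound


def _synthesis_alpha(x_delayed, p: ModelParams):
    if p.constitutive_only:
        return p.c0
    p_free, p_bound = promoter_occupancy(x_delayed, p.kp)
    return p.c0 * p_free + p.c1 * p_bound


def _synthesis_eps(x_delayed, p: ModelParams):
    p_free, p_bound = promoter_occupancy(x_delayed, p.kp)
    return p.eps * (p.c0_e * p_free + p.c1 * p_bound)


def _removal_rate(x_now, k_now: float, deg: float, p: ModelParams):
    """Per-unit loss rate of a total inhibitor pool at instantaneous x."""
    f_free, f_bound = complex_fractions(x_now, p)
    return deg * f_free + p.r_ikk * k_now * (f_free + p.rho * f_bound)


def rhs_dual(state, delayed_tau1, delayed_tau2, k_now: float, p: ModelParams):
    """Time derivatives (dy_a/dt, dy_e/dt) of the dual-feedback model.

    Each isoform's synthesis reads nuclear NF-κB at its own delay: IκBα
    synthesis sees the state at ``t - tau1``, IκBε at ``t - (tau1 + tau2)``
    (its pipeline trails IκBα's by the increment ``tau2``).
    Degradation acts on the instantaneous free/bound partition: constitutive
    turnover removes free inhibitor only, while IKK-mediated degradation
    removes free inhibitor at rate ``r_ikk * K`` and complexed inhibitor at
    ``rho * r_ikk * K`` (releasing NF-κB, which the algebra accounts for).

    Parameters
    ----------
    state, delayed_tau1, delayed_tau2 : (y_a, y_e) pairs
        Total inhibitor levels now, at ``t - tau1``, and at the ε reading
        time ``t - (tau1 + tau2)``, nM.
    k_now : float
        Current IKK activity.
    """
    y_a, y_e = state
    x_now = solve_free_nfkb(y_a, y_e, p)
    x_tau1 = solve_free_nfkb(delayed_tau1[0], delayed_tau1[1], p)
    dy_a = _synthesis_alpha(x_tau1, p) - _removal_rate(x_now, k_now, p.deg_a, p) * y_a
    if p.eps == 0.0 and y_e == 0.0:
        dy_e = 0.0
    else:
        x_tau2 = solve_free_nfkb(delayed_tau2[0], delayed_tau2[1], p)
        dy_e = _synthesis_eps(x_tau2, p) - _removal_rate(x_now, k_now, p.deg_e, p) * y_e
    return dy_a, dy_e


def rhs_single(y_now: float, y_delayed: float, k_now: float, p: ModelParams) -> float:
    """dy/dt of the single-feedback model (total IκBα only).

    Exactly the IκBα component of :func:`rhs_dual` with the ε-loop removed,
    evaluated in the same order so the reduction is bitwise.
    """
    return rhs_dual((y_now, 0.0), (y_delayed, 0.0), (y_delayed, 0.0), k_now, p)[0]
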