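"""Numba inner loop for the delayed stochastic simulation algorithm.

Exact SSA after Gillespie with the delayed-reaction modification: delayed
channels fire (are *initiated*) according to their instantaneous
propensity, but their product update is applied only after the channel's
delay. Initiations consume nothing; completions are queued and interleaved
with instantaneous events in time order. Piecewise-constant input K(t) is
handled by inserting barrier events at the switch times, at which the
clock advances without a reaction (valid by memorylessness of the
exponential waiting time).

Reaction encoding (all arrays over reactions r and species s):
  rate[r]        stochastic rate constant (1/min, molecule units)
  ri1[r], ri2[r] reactant species indices for the propensity product
                 (-1 for none); propensity = rate * X[ri1] * X[ri2]
  k_dep[r]       1 if the propensity is proportional to the input K(t)
  delay[r]       completion delay, min (0 = instantaneous)
  stoich_now[r]  state change applied at initiation
  stoich_done[r] state change applied at completion (delayed channels)
"""

from __future__ import annotations

import numpy as np
from numba import njit

_QUEUE_CAP = 1 << 20


@njit(cache=True)
def _heap_push(times, rxns, n, t, r):
    i = n
    times[i] = t
    rxns[i] = r
    while i > 0:
        par = (i - 1) >> 1
        if times[par] <= times[i]:
            break
        times[par], times[i] = times[i], times[par]
        rxns[par], rxns[i] = rxns[i], rxns[par]
        i = par
    return n + 1


@njit(cache=True)
def _heap_pop(times, rxns, n):
    t0 = times[0]
    r0 = rxns[0]
    n -= 1
    times[0] = times[n]
    rxns[0] = rxns[n]
    i = 0
    while True:
        l = 2 * i + 1
        rgt = l + 1
        small = i
        if l < n and times[l] < times[small]:
            small = l
        if rgt < n and times[rgt] < times[small]:
            small = rgt
        if small == i:
            break
        times[small], times[i] = times[i], times[small]
        rxns[small], rxns[i] = rxns[i], rxns[small]
        i = small
    return t0, r0, n


@njit(cache=True)
def run_ssa(
    init,          # int64[n_species]
    rate,          # float64[n_rxn]
    ri1, ri2,      # int64[n_rxn]
    k_dep,         # uint8[n_rxn]
    delay,         # float64[n_rxn]
    stoich_now,    # int64[n_rxn, n_species]
    stoich_done,   # int64[n_rxn, n_species]
    switch_t,      # float64[n_switch] sorted times where K changes
    k_vals,        # float64[n_switch + 1] K on each inter-switch interval
    grid,          # float64[n_grid] sample times (sorted, >= 0)
    seed,          # int64
    warm_t,        # float64[n_warm] completion times of pre-t0 initiations
    warm_r,        # int64[n_warm] their reaction indices
):
    """One realization; returns (samples[n_grid, n_species], n_events, status).

    status: 0 ok, 1 pending-queue overflow.
    """
    np.random.seed(seed)
    n_rxn = rate.shape[0]
    n_species = init.shape[0]
    n_grid = grid.shape[0]

    x = init.copy()
    samples = np.zeros((n_grid, n_species), dtype=np.int64)
    pend_t = np.empty(_QUEUE_CAP, dtype=np.float64)
    pend_r = np.empty(_QUEUE_CAP, dtype=np.int64)
    n_pend = 0
    for i in range(warm_t.shape[0]):
        n_pend = _heap_push(pend_t, pend_r, n_pend, warm_t[i], warm_r[i])

    t = 0.0
    t_end = grid[n_grid - 1]
    gi = 0
    si = 0  # index of next switch time
    n_events = 0
    prop = np.empty(n_rxn, dtype=np.float64)

    while True:
        k_now = k_vals[si]
        a0 = 0.0
        for r in range(n_rxn):
            a = rate[r]
            if ri1[r] >= 0:
                a *= x[ri1[r]]
            if ri2[r] >= 0:
                a *= x[ri2[r]]
            if k_dep[r] == 1:
                a *= k_now
            prop[r] = a
            a0 += a

        if a0 > 0.0:
            t_rxn = t - np.log(np.random.random()) / a0
        else:
            t_rxn = np.inf
        t_pend = pend_t[0] if n_pend > 0 else np.inf
        t_switch = switch_t[si] if si < switch_t.shape[0] else np.inf

        t_next = min(t_rxn, t_pend, t_switch)

        # emit grid samples strictly before the next state change
        while gi < n_grid and grid[gi] < t_next:
            for s in range(n_species):
                samples[gi, s] = x[s]
            gi += 1
        if gi >= n_grid or t_next > t_end:
            while gi < n_grid:
                for s in range(n_species):
                    samples[gi, s] = x[s]
                gi += 1
            return samples, n_events, 0

        if t_pend <= t_switch and t_pend <= t_rxn:
            tp, rp, n_pend = _heap_pop(pend_t, pend_r, n_pend)
            t = tp
            for s in range(n_species):
                x[s] += stoich_done[rp, s]
            n_events += 1
        elif t_switch <= t_rxn:
            t = t_switch
            si += 1  # propensities re-evaluated at loop top
        else:
            t = t_rxn
            u = np.random.random() * a0
            acc = 0.0
            rsel = n_rxn - 1
            for r in range(n_rxn):
                acc += prop[r]
                if u < acc:
                    rsel = r
                    break
            for s in range(n_species):
                x[s] += stoich_now[rsel, s]
            if delay[rsel] > 0.0:
                if n_pend >= _QUEUE_CAP:
                    return samples, n_events, 1
                n_pend = _heap_push(pend_t, pend_r, n_pend, t + delay[rsel], rsel)
            n_events += 1
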