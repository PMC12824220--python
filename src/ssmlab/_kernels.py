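"""Numba kernels for trial-level simulation and inverse binomial sampling.

Everything here is deliberately flat: scalar loops over trials, explicit
random state seeded once per call, no allocation inside the hot loops.
The public modules wrap these with validated, documented interfaces.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Outcome codes shared by both simulators: +1 = upper bound / accumulator 1,
# -1 = lower bound / accumulator 2, 0 = omission (deadline reached).
OMISSION = 0


@njit(cache=True, inline="always")
def _ddm_one(v, a, theta, z, t0, p_outlier, dt, deadline):
    """One DDM first passage. Returns (choice, rt); rt is NaN on omission."""
    if p_outlier > 0.0 and np.random.random() < p_outlier:
        choice = 1 if np.random.random() < 0.5 else -1
        return choice, np.random.random() * deadline
    x = a * (2.0 * z - 1.0)
    n_steps = int((deadline - t0) / dt)  # last crossing check at n_steps * dt
    sq = np.sqrt(dt)
    step = 0
    while True:
        t = step * dt
        bound = a - theta * t
        if bound <= 0.0:
            # fully collapsed bound: side with more evidence wins now
            if x > 0.0:
                return 1, t + t0
            elif x < 0.0:
                return -1, t + t0
            else:
                return (1 if np.random.random() < 0.5 else -1), t + t0
        if x >= bound:
            return 1, t + t0
        if x <= -bound:
            return -1, t + t0
        if step >= n_steps:
            return OMISSION, np.nan
        x_new = x + v * dt + np.random.normal() * sq
        if -bound < x_new < bound:
            # Brownian-bridge correction for within-step barrier crossings;
            # removes the O(sqrt(dt)) bias of naive Euler absorption.
            du = (bound - x) * (bound - x_new)
            dl = (bound + x) * (bound + x_new)
            p_up = np.exp(-2.0 * du / dt) if du < 10.4 * dt else 0.0
            p_lo = np.exp(-2.0 * dl / dt) if dl < 10.4 * dt else 0.0
            if p_up + p_lo > 0.0:
                u = np.random.random()
                if u < p_up:
                    return 1, t + dt + t0
                elif u < p_up + p_lo:
                    return -1, t + dt + t0
        x = x_new
        step += 1


@njit(cache=True)
def ddm_batch(v, a, theta, z, t0, p_outlier, dt, deadline, seed):
    """Simulate one outcome per trial given per-trial parameter arrays."""
    np.random.seed(seed)
    n = v.shape[0]
    choices = np.zeros(n, dtype=np.int64)
    rts = np.full(n, np.nan)
    for i in range(n):
        c, rt = _ddm_one(v[i], a[i], theta[i], z[i], t0[i], p_outlier[i], dt, deadline)
        choices[i] = c
        rts[i] = rt
    return choices, rts


@njit(cache=True, inline="always")
def _lca_one(i1, i2, k, w, a0, c, sigma, t0, dt, deadline, printed_inhibition):
    """One rectified-LCA race. Returns (winner, rt); winner 0 = omission."""
    y1 = 0.0
    y2 = 0.0
    n_steps = int((deadline - t0) / dt)
    sq = np.sqrt(dt)
    step = 0
    while True:
        t = step * dt
        bound = a0 - c * t
        if bound <= 0.0:
            if y1 > y2:
                return 1, t + t0
            elif y2 > y1:
                return -1, t + t0
            else:
                return (1 if np.random.random() < 0.5 else -1), t + t0
        hit1 = y1 >= bound
        hit2 = y2 >= bound
        if hit1 and hit2:
            if y1 > y2:
                return 1, t + t0
            elif y2 > y1:
                return -1, t + t0
            else:
                return (1 if np.random.random() < 0.5 else -1), t + t0
        elif hit1:
            return 1, t + t0
        elif hit2:
            return -1, t + t0
        if step >= n_steps:
            return OMISSION, np.nan
        inh2 = y2 if printed_inhibition else y1
        y1n = y1 + dt * (i1 - k * y1 - w * y2) + np.random.normal() * sigma * sq
        y2n = y2 + dt * (i2 - k * y2 - w * inh2) + np.random.normal() * sigma * sq
        y1 = y1n if y1n > 0.0 else 0.0
        y2 = y2n if y2n > 0.0 else 0.0
        step += 1


@njit(cache=True)
def lca_batch(i1, i2, k, w, a0, c, sigma, t0, dt, deadline, seed, printed_inhibition):
    np.random.seed(seed)
    n = i1.shape[0]
    choices = np.zeros(n, dtype=np.int64)
    rts = np.full(n, np.nan)
    for i in range(n):
        ch, rt = _lca_one(
            i1[i], i2[i], k, w, a0, c, sigma, t0, dt, deadline, printed_inhibition
        )
        choices[i] = ch
        rts[i] = rt
    return choices, rts


@njit(cache=True)
def lca_trajectory(i1, i2, k, w, a0, c, sigma, t0, dt, deadline, seed, printed_inhibition):
    """One LCA trial recording the activation path (for diagnostics/tests)."""
    np.random.seed(seed)
    nmax = int(np.ceil((deadline - t0) / dt)) + 1
    path = np.zeros((nmax, 2))
    y1 = 0.0
    y2 = 0.0
    sq = np.sqrt(dt)
    n_used = 0
    for step in range(nmax):
        path[step, 0] = y1
        path[step, 1] = y2
        n_used = step + 1
        t = step * dt
        bound = a0 - c * t
        if bound <= 0.0 or y1 >= bound or y2 >= bound:
            break
        inh2 = y2 if printed_inhibition else y1
        y1n = y1 + dt * (i1 - k * y1 - w * y2) + np.random.normal() * sigma * sq
        y2n = y2 + dt * (i2 - k * y2 - w * inh2) + np.random.normal() * sigma * sq
        y1 = y1n if y1n > 0.0 else 0.0
        y2 = y2n if y2n > 0.0 else 0.0
    return path[:n_used]


@njit(cache=True, inline="always")
def _categorize(choice, rt, correct_choice, flag, edges, n_bins):
    """Map a simulated outcome onto a stratified RT-bin category id.

    Layout: responded categories are stratum * n_bins + bin with
    stratum = 2 * flag + is_correct; omissions occupy the trailing
    categories n_strata * n_bins + flag.  Edges are right-closed.
    """
    n_strata = edges.shape[0]
    if choice == OMISSION:
        return n_strata * n_bins + flag
    is_correct = 1 if choice == correct_choice else 0
    stratum = 2 * flag + is_correct
    b = 0
    n_edges = edges.shape[1]
    while b < n_edges and rt > edges[stratum, b]:
        b += 1
    return stratum * n_bins + b


@njit(cache=True)
def categorize_batch(choices, rts, correct_choice, flags, edges, n_bins):
    n = choices.shape[0]
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        out[i] = _categorize(choices[i], rts[i], correct_choice[i], flags[i], edges, n_bins)
    return out


@njit(cache=True)
def ibs_ddm(
    obs_cat,
    v,
    a,
    theta,
    z,
    t0,
    p_outlier,
    correct_choice,
    flags,
    edges,
    n_bins,
    dt,
    deadline,
    k_max,
    harmonic,
    seed,
    ll_floor,
):
    """One IBS pass over all trials for a DDM simulator.

    Returns (log-likelihood estimate, number of trials that hit k_max).
    ``harmonic[k]`` must hold sum_{j=1}^{k} 1/j with harmonic[0] = 0.
    Per-trial contributions are non-positive, so once the running sum
    falls below ``ll_floor`` the final value is provably below it and the
    pass aborts early (the partial sum is returned).
    """
    np.random.seed(seed)
    total = 0.0
    n_capped = 0
    n = obs_cat.shape[0]
    for i in range(n):
        k = 0
        while True:
            k += 1
            ch, rt = _ddm_one(v[i], a[i], theta[i], z[i], t0[i], p_outlier[i], dt, deadline)
            cat = _categorize(ch, rt, correct_choice[i], flags[i], edges, n_bins)
            if cat == obs_cat[i]:
                total -= harmonic[k - 1]
                break
            if k >= k_max:
                total -= harmonic[k_max - 1]
                n_capped += 1
                break
        if total < ll_floor:
            return total, n_capped
    return total, n_capped


@njit(cache=True)
def ibs_lca(
    obs_cat,
    i1,
    i2,
    k_leak,
    w,
    a0,
    c,
    sigma,
    t0,
    correct_choice,
    flags,
    edges,
    n_bins,
    dt,
    deadline,
    k_max,
    harmonic,
    seed,
    printed_inhibition,
    ll_floor,
):
    """One IBS pass over all trials for the LCA simulator."""
    np.random.seed(seed)
    total = 0.0
    n_capped = 0
    n = obs_cat.shape[0]
    for i in range(n):
        k = 0
        while True:
            k += 1
            ch, rt = _lca_one(
                i1[i], i2[i], k_leak, w, a0, c, sigma, t0, dt, deadline, printed_inhibition
            )
            cat = _categorize(ch, rt, correct_choice[i], flags[i], edges, n_bins)
            if cat == obs_cat[i]:
                total -= harmonic[k - 1]
                break
            if k >= k_max:
                total -= harmonic[k_max - 1]
                n_capped += 1
                break
        if total < ll_floor:
            return total, n_capped
    return total, n_capped
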