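"""Numba hot loops for the exact stochastic simulator.

The four-type birth-death-mutation process is sampled exactly via Poisson
thinning: between state changes the candidate-event rate is bounded by
``N * (cfW * comp + g)``, which dominates every actual rate at any later
time because all Hill factors are <= 1, the falling factors only decrease,
and the competition term ``comp = 1 - N/K`` is constant until the next
accepted event.  Candidates are accepted with probability
(actual total rate)/(bound) and then attributed to a specific event.

Outcome codes: 0 extinct, 1 rescued by wildtype, 2 rescued by mutator,
3 persisted to t_end without rescue, 4 population cap exceeded.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["replicate_kernel", "ensemble_kernel", "oracle_kernel", "oracle_ensemble_kernel"]


@njit(cache=True, fastmath=True)
def replicate_kernel(
    seed,
    w,
    m,
    rw,
    rm,
    K,
    g,
    cfW,
    cfM,
    theta,
    n,
    n_rise,
    mu,
    mu_p,
    mu_M,
    frozen,
    t_end,
    rescue_threshold,
    cap,
    chk_times,
    chk_counts,
    ev_times,
    ev_codes,
):
    """Simulate one replicate; returns (outcome, mutator_fixed, t, w, m, rw, rm, n_events).

    ``chk_times``/``chk_counts``: optional checkpoint grid; the state just
    before each checkpoint time is written into ``chk_counts`` (n_chk x 4).
    ``ev_times``/``ev_codes``: optional accepted-event log (codes 0-3 birth
    into type, 4-7 death of type, in W/M/RW/RM order).
    """
    np.random.seed(seed)
    t = 0.0
    ci = 0
    n_chk = chk_times.shape[0]
    max_ev = ev_times.shape[0]
    n_ev = 0
    outcome = 3
    while True:
        N = w + m + rw + rm
        if N == 0:
            outcome = 0
            break
        if N > cap:
            outcome = 4
            break
        comp = 1.0 - N / K
        if comp < 0.0:
            comp = 0.0
        bound = N * (cfW * comp + g)
        t_new = t - np.log(1.0 - np.random.random()) / bound
        while ci < n_chk and chk_times[ci] <= t_new:
            chk_counts[ci, 0] = w
            chk_counts[ci, 1] = m
            chk_counts[ci, 2] = rw
            chk_counts[ci, 3] = rm
            ci += 1
        t = t_new
        if t >= t_end:
            if rw + rm >= 1:
                outcome = 2 if rm > rw else 1
            else:
                outcome = 3
            break
        if frozen:
            dec = 1.0
            ris = 0.0
        else:
            x = (t / theta) ** n
            dec = 1.0 / (1.0 + x)
            if n_rise == n:
                ris = x * dec
            else:
                xr = (t / theta) ** n_rise
                ris = xr / (1.0 + xr)
        bw = cfW * dec * comp * w
        bm = cfM * dec * comp * m
        brw = cfW * ris * comp * rw
        brm = cfM * ris * comp * rm
        total = bw + bm + brw + brm + g * N
        u = np.random.random() * bound
        if u >= total:
            continue  # thinned candidate
        code = -1
        if u < bw:
            v = np.random.random()
            if v < mu_M:
                m += 1
                code = 1
            elif v < mu_M + mu:
                rw += 1
                code = 2
            else:
                w += 1
                code = 0
        elif u < bw + bm:
            v = np.random.random()
            if v < mu_p:
                rm += 1
                code = 3
            else:
                m += 1
                code = 1
        elif u < bw + bm + brw:
            rw += 1
            code = 2
        elif u < bw + bm + brw + brm:
            rm += 1
            code = 3
        else:
            z = np.random.random() * N
            if z < w:
                w -= 1
                code = 4
            elif z < w + m:
                m -= 1
                code = 5
            elif z < w + m + rw:
                rw -= 1
                code = 6
            else:
                rm -= 1
                code = 7
        if n_ev < max_ev:
            ev_times[n_ev] = t
            ev_codes[n_ev] = code
        n_ev += 1
        if rw + rm >= rescue_threshold:
            outcome = 2 if rm > rw else 1
            break
    while ci < n_chk:
        chk_counts[ci, 0] = w
        chk_counts[ci, 1] = m
        chk_counts[ci, 2] = rw
        chk_counts[ci, 3] = rm
        ci += 1
    mut_fixed = 1 if (w == 0 and rw == 0 and (m + rm) > 0) else 0
    return outcome, mut_fixed, t, w, m, rw, rm, n_ev


@njit(cache=True, fastmath=True)
def ensemble_kernel(
    seeds,
    w0,
    m0,
    K,
    g,
    cfW,
    cfM,
    theta,
    n,
    n_rise,
    mu,
    mu_p,
    mu_M,
    frozen,
    t_end,
    rescue_threshold,
    cap,
    chk_times,
):
    """Run independent replicates from per-replicate seeds.

    Returns (outcomes, mutator_fixed, t_final, final_counts, chk_NW) where
    chk_NW[i, j] is replicate i's wildtype+mutator (non-rescue) population
    at checkpoint j.
    """
    n_rep = seeds.shape[0]
    n_chk = chk_times.shape[0]
    outcomes = np.empty(n_rep, dtype=np.int64)
    fixed = np.empty(n_rep, dtype=np.int64)
    t_final = np.empty(n_rep, dtype=np.float64)
    finals = np.empty((n_rep, 4), dtype=np.int64)
    chk_NW = np.zeros((n_rep, n_chk), dtype=np.float64)
    chk_counts = np.zeros((n_chk, 4), dtype=np.int64)
    no_ev_t = np.zeros(0, dtype=np.float64)
    no_ev_c = np.zeros(0, dtype=np.int64)
    for i in range(n_rep):
        for j in range(n_chk):
            for k in range(4):
                chk_counts[j, k] = 0
        out, mf, t, w, m, rw, rm, _ = replicate_kernel(
            seeds[i],
            w0,
            m0,
            0,
            0,
            K,
            g,
            cfW,
            cfM,
            theta,
            n,
            n_rise,
            mu,
            mu_p,
            mu_M,
            frozen,
            t_end,
            rescue_threshold,
            cap,
            chk_times,
            chk_counts,
            no_ev_t,
            no_ev_c,
        )
        outcomes[i] = out
        fixed[i] = mf
        t_final[i] = t
        finals[i, 0] = w
        finals[i, 1] = m
        finals[i, 2] = rw
        finals[i, 3] = rm
        for j in range(n_chk):
            chk_NW[i, j] = chk_counts[j, 0] + chk_counts[j, 1]
    return outcomes, fixed, t_final, finals, chk_NW


@njit(cache=True, fastmath=True)
def oracle_kernel(
    seed,
    t0,
    times,
    comp,
    theta,
    n,
    n_rise,
    cfA,
    cfR,
    g,
    mu_p,
    two_type,
    supercrit_end,
    t_max,
):
    """One founder lineage, time-dependent rates read from a trajectory.

    ``two_type``: founder is a non-rescue mutator (type A, falling Hill,
    cost cfA) whose offspring carry the rescue allele with probability
    mu_p; otherwise the founder is itself a rescue mutant (type R, rising
    Hill, cost cfR).  No feedback on the resident trajectory.

    Fixation is declared once k * ln(b_R/g) > 20 for the current R count k
    and per-capita rate b_R (residual extinction probability <= e^-20,
    valid because the effective rescue rate is nondecreasing in time).
    Returns 1 on fixation, 0 on loss.
    """
    np.random.seed(seed)
    a = 1 if two_type else 0
    rcount = 0 if two_type else 1
    t = t0
    cf_max = cfA if cfA > cfR else cfR
    events = 0
    while True:
        ntot = a + rcount
        if ntot == 0:
            return 0
        bound = ntot * (cf_max + g)
        t -= np.log(1.0 - np.random.random()) / bound
        if t > t_max and not supercrit_end:
            return 0
        c = np.interp(t, times, comp)
        x = (t / theta) ** n
        dec = 1.0 / (1.0 + x)
        if n_rise == n:
            ris = x * dec
        else:
            xr = (t / theta) ** n_rise
            ris = xr / (1.0 + xr)
        bA = cfA * dec * c
        bR = cfR * ris * c
        if rcount > 0 and bR > g:
            if rcount * np.log(bR / g) > 20.0:
                return 1
        total = bA * a + bR * rcount + g * ntot
        u = np.random.random() * bound
        if u >= total:
            continue
        if u < bA * a:
            if np.random.random() < mu_p:
                rcount += 1
            else:
                a += 1
        elif u < bA * a + bR * rcount:
            rcount += 1
        else:
            z = np.random.random() * ntot
            if z < a:
                a -= 1
            else:
                rcount -= 1
        events += 1
        if events > 20_000_000:
            # pathological near-critical meander; count as loss
            return 0


@njit(cache=True, fastmath=True)
def oracle_ensemble_kernel(
    seeds,
    t0,
    times,
    comp,
    theta,
    n,
    n_rise,
    cfA,
    cfR,
    g,
    mu_p,
    two_type,
    supercrit_end,
    t_max,
):
    wins = 0
    for i in range(seeds.shape[0]):
        wins += oracle_kernel(
            seeds[i],
            t0,
            times,
            comp,
            theta,
            n,
            n_rise,
            cfA,
            cfR,
            g,
            mu_p,
            two_type,
            supercrit_end,
            t_max,
        )
    return wins
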