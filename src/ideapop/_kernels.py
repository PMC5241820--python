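"""Hot loops for exact stochastic simulation (numba-accelerated).

All kernels draw exponential waiting times from the total exit rate and pick
the event proportionally to the individual rates (Gillespie's direct method).
Each kernel seeds its own generator, so a (kernel, seed) pair is bit-
reproducible.  If numba is unavailable the same code runs as plain python.

Status codes: 0 = absorbed, 1 = hit t_max, 2 = hit max_events (censored).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

ABSORBED, HIT_TMAX, CENSORED = 0, 1, 2


@njit(cache=True)
def gillespie_1d(tplus, tminus, n0, seed, t_max, max_events):
    """Simulate the 1D chain; return (n_final, t_final, status, n_events)."""
    np.random.seed(seed)
    n = n0
    t = 0.0
    ev = 0
    while ev < max_events:
        up = tplus[n]
        dn = tminus[n]
        tot = up + dn
        if tot <= 0.0:
            return n, t, ABSORBED, ev
        dt = np.random.exponential(1.0 / tot)
        if t + dt > t_max:
            return n, t_max, HIT_TMAX, ev
        t += dt
        if np.random.random() * tot < up:
            n += 1
        else:
            n -= 1
        ev += 1
    return n, t, CENSORED, ev


@njit(cache=True)
def gillespie_1d_record(tplus, tminus, n0, seed, t_max, max_events,
                        out_t, out_n):
    """Recording variant; fills out_t/out_n (len >= max_events+1).

    Returns (n_final, t_final, status, n_records).
    """
    np.random.seed(seed)
    n = n0
    t = 0.0
    out_t[0] = 0.0
    out_n[0] = n
    k = 1
    ev = 0
    while ev < max_events:
        up = tplus[n]
        dn = tminus[n]
        tot = up + dn
        if tot <= 0.0:
            return n, t, ABSORBED, k
        dt = np.random.exponential(1.0 / tot)
        if t + dt > t_max:
            return n, t_max, HIT_TMAX, k
        t += dt
        if np.random.random() * tot < up:
            n += 1
        else:
            n -= 1
        out_t[k] = t
        out_n[k] = n
        k += 1
        ev += 1
    return n, t, CENSORED, k


@njit(cache=True)
def gillespie_2d(ap, am, bp, bm, n0, m0, seed, t_max, max_events):
    """Simulate the two-population chain on the (n, m) lattice.

    Returns (n_final, m_final, t_final, status, n_events).
    """
    np.random.seed(seed)
    n = n0
    m = m0
    t = 0.0
    ev = 0
    while ev < max_events:
        r0 = ap[n, m]
        r1 = am[n, m]
        r2 = bp[n, m]
        r3 = bm[n, m]
        tot = r0 + r1 + r2 + r3
        if tot <= 0.0:
            return n, m, t, ABSORBED, ev
        dt = np.random.exponential(1.0 / tot)
        if t + dt > t_max:
            return n, m, t_max, HIT_TMAX, ev
        t += dt
        u = np.random.random() * tot
        if u < r0:
            n += 1
        elif u < r0 + r1:
            n -= 1
        elif u < r0 + r1 + r2:
            m += 1
        else:
            m -= 1
        ev += 1
    return n, m, t, CENSORED, ev


@njit(cache=True)
def gillespie_2d_record(ap, am, bp, bm, n0, m0, seed, t_max, max_events,
                        out_t, out_n, out_m):
    np.random.seed(seed)
    n = n0
    m = m0
    t = 0.0
    out_t[0] = 0.0
    out_n[0] = n
    out_m[0] = m
    k = 1
    ev = 0
    while ev < max_events:
        r0 = ap[n, m]
        r1 = am[n, m]
        r2 = bp[n, m]
        r3 = bm[n, m]
        tot = r0 + r1 + r2 + r3
        if tot <= 0.0:
            return n, m, t, ABSORBED, k
        dt = np.random.exponential(1.0 / tot)
        if t + dt > t_max:
            return n, m, t_max, HIT_TMAX, k
        t += dt
        u = np.random.random() * tot
        if u < r0:
            n += 1
        elif u < r0 + r1:
            n -= 1
        elif u < r0 + r1 + r2:
            m += 1
        else:
            m -= 1
        out_t[k] = t
        out_n[k] = n
        out_m[k] = m
        k += 1
        ev += 1
    return n, m, t, CENSORED, k


@njit(cache=True)
def gillespie_2d_sampled(ap, am, bp, bm, n0, m0, seed, sample_times,
                         max_events, out_n, out_m):
    """Record the lattice state at fixed sample times (piecewise constant).

    After absorption the state stays at the absorbing corner.  Returns
    (status, n_events, t_final).
    """
    np.random.seed(seed)
    n = n0
    m = m0
    t = 0.0
    ks = 0
    n_samples = sample_times.shape[0]
    ev = 0
    while ev < max_events:
        r0 = ap[n, m]
        r1 = am[n, m]
        r2 = bp[n, m]
        r3 = bm[n, m]
        tot = r0 + r1 + r2 + r3
        if tot <= 0.0:
            while ks < n_samples:
                out_n[ks] = n
                out_m[ks] = m
                ks += 1
            return ABSORBED, ev, t
        dt = np.random.exponential(1.0 / tot)
        while ks < n_samples and sample_times[ks] < t + dt:
            out_n[ks] = n
            out_m[ks] = m
            ks += 1
        if ks >= n_samples:
            return HIT_TMAX, ev, t
        t += dt
        u = np.random.random() * tot
        if u < r0:
            n += 1
        elif u < r0 + r1:
            n -= 1
        elif u < r0 + r1 + r2:
            m += 1
        else:
            m -= 1
        ev += 1
    while ks < n_samples:
        out_n[ks] = n
        out_m[ks] = m
        ks += 1
    return CENSORED, ev, t


@njit(cache=True)
def triplet_sim(a11, a12, a21, a22, N, Gamma, n0, n_events, seed, restart):
    """Microscopic triplet-sampling process (payoff-based fitness only).

    Per event an ordered triplet (primary, secondary, adversary) is drawn
    with replacement from the population; primary and secondary both play the
    adversary, and the secondary is switched to the primary's type with
    probability g = [1 + Gamma*(a_prim - a_sec)]/2.

    With ``restart`` the population is reset to n0 whenever it absorbs, so
    interior transition statistics keep accumulating; the per-state
    probabilities are unaffected (the chain is Markov in n).

    Returns (visits, ups, downs, n_final): per-state event counts and the
    counts of composition-increasing/-decreasing events.
    """
    np.random.seed(seed)
    visits = np.zeros(N + 1, dtype=np.int64)
    ups = np.zeros(N + 1, dtype=np.int64)
    downs = np.zeros(N + 1, dtype=np.int64)
    n = n0
    for _ in range(n_events):
        if restart and (n == 0 or n == N):
            n = n0
        visits[n] += 1
        if n == 0 or n == N:
            continue
        x = n / N
        # types: 1 with prob x, 2 otherwise; with replacement
        t1 = 1 if np.random.random() < x else 2
        t2 = 1 if np.random.random() < x else 2
        ta = 1 if np.random.random() < x else 2
        if t1 == t2:
            continue  # replacement cannot change the composition
        if ta == 1:
            pay1, pay2 = a11, a21
        else:
            pay1, pay2 = a12, a22
        if t1 == 1:
            g = 0.5 * (1.0 + Gamma * (pay1 - pay2))
        else:
            g = 0.5 * (1.0 + Gamma * (pay2 - pay1))
        if np.random.random() < g:
            if t1 == 1:
                ups[n] += 1
                n += 1
            else:
                downs[n] += 1
                n -= 1
    return visits, ups, downs, n
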