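"""Exact birth-death chains for finite populations of ideas.

A player's mind holds N idea-tokens, each one of two pure strategies; the
state is the count n of type-1 tokens.  Transitions n -> n+-1 occur with
rates

    T+_n = N * x * (1-x) * g(f1, f2),      x = n/N,
    T-_n = N * x * (1-x) * g(f2, f1),

where g(f1, f2) = [1 + Gamma*(f1 - f2)]/2 is the linear pairwise comparison
probability and f_i = pi_i - lam*ln(x_i) the entropically modified fitness
(pi_i the finite-population average payoff).  The explicit factor N means
time is measured in generations.  States n = 0 and n = N are absorbing:
unlike mutation, memory loss does not rescue an extinct idea.

Positivity of the rates requires g in [0, 1] at every interior state, which
bounds lam at fixed Gamma (roughly lam < O(1/ln N)); ``validate_rates``
checks this and reports the admissible lam.  g is deliberately *not*
clipped: out-of-range g is a modelling error, not a numerical one.

The two-population version runs one such chain per player on the (n, m)
lattice, each population's payoffs evaluated against the other's composition;
its only absorbing states are the four corners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from . import _kernels
from .dynamics import avg_payoff_1d, avg_payoff_2d
from .games import PayoffBimatrix, PayoffMatrix

__all__ = [
    "ChainParams",
    "BirthDeathRates1D",
    "TwoPopRates",
    "Trajectory",
    "RateDiagnostic",
    "pairwise_comparison_g",
    "rates_1d",
    "rates_2d",
    "validate_rates",
    "gillespie",
    "run_ensemble",
    "triplet_microsim",
    "replicate_seeds",
    "TripletCounts",
]

DEFAULT_MAX_EVENTS = 10 ** 9


@dataclass(frozen=True)
class ChainParams:
    """Finite-chain parameters: population size N, selection Gamma, memory lam."""

    N: int
    Gamma: float = 0.1
    lam: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.Gamma < 0 or self.lam < 0:
            raise ValueError("Gamma and lam must be >= 0")


@dataclass
class BirthDeathRates1D:
    tplus: np.ndarray   # shape (N+1,)
    tminus: np.ndarray
    N: int

    def absorbing_states(self) -> list:
        tot = self.tplus + self.tminus
        return [int(n) for n in np.nonzero(tot == 0.0)[0]]


@dataclass
class TwoPopRates:
    aplus: np.ndarray   # (N+1, N+1): (n,m) -> (n+1,m)
    aminus: np.ndarray
    bplus: np.ndarray   # (n,m) -> (n,m+1)
    bminus: np.ndarray
    N: int

    def total_exit(self) -> np.ndarray:
        return self.aplus + self.aminus + self.bplus + self.bminus

    def absorbing_states(self) -> list:
        tot = self.total_exit()
        idx = np.argwhere(tot == 0.0)
        return [(int(n), int(m)) for n, m in idx]


@dataclass
class Trajectory:
    times: Optional[np.ndarray]      # event times (recorded runs only)
    states: Optional[np.ndarray]     # (k,) counts or (k, 2) lattice states
    absorbed: bool
    censored: bool                   # hit max_events
    hit_tmax: bool
    absorption_state: Optional[tuple]
    absorption_time: Optional[float]
    final_state: tuple
    final_time: float
    n_events: int


@dataclass
class RateDiagnostic:
    ok: bool
    bad_states: list
    g_min: float
    g_max: float
    lam_max: Optional[float] = None   # largest admissible lam at this Gamma

    def __bool__(self) -> bool:
        return self.ok


def pairwise_comparison_g(f1, f2, Gamma: float):
    """Linear pairwise comparison probability g = [1 + Gamma*(f1 - f2)]/2.

    The linear form makes T+ - T- proportional to Gamma*(f1 - f2), which is
    exactly the (modified) replicator drift.  Values outside [0, 1] are
    returned as-is; range enforcement is validate_rates' job.
    """
    return 0.5 * (1.0 + Gamma * (np.asarray(f1, dtype=float) - f2))


def _fitness_1d(matrix: PayoffMatrix, N: int, lam: float):
    """f1, f2 on interior states n = 1..N-1 (finite-population payoffs)."""
    n = np.arange(1, N)
    x = n / N
    pi1, pi2 = avg_payoff_1d(matrix, x)
    f1 = pi1 - (lam * np.log(x) if lam else 0.0)
    f2 = pi2 - (lam * np.log(1.0 - x) if lam else 0.0)
    return n, x, f1, f2


def rates_1d(matrix: PayoffMatrix, params: ChainParams,
             check: bool = True) -> BirthDeathRates1D:
    """Birth-death rates of the single-population chain (absorbing at 0, N)."""
    N = params.N
    tplus = np.zeros(N + 1)
    tminus = np.zeros(N + 1)
    n, x, f1, f2 = _fitness_1d(matrix, N, params.lam)
    base = N * x * (1.0 - x)
    tplus[n] = base * pairwise_comparison_g(f1, f2, params.Gamma)
    tminus[n] = base * pairwise_comparison_g(f2, f1, params.Gamma)
    rates = BirthDeathRates1D(tplus=tplus, tminus=tminus, N=N)
    if check:
        diag = validate_rates(rates)
        if not diag.ok:
            raise ValueError(
                f"invalid rates (g outside [0,1]) at states {diag.bad_states[:5]}; "
                f"reduce lam or Gamma (g range [{diag.g_min:.3g}, {diag.g_max:.3g}])"
            )
    return rates


def rates_2d(bimatrix: PayoffBimatrix, params: ChainParams,
             check: bool = True) -> TwoPopRates:
    """Transition rates of the two-population chain over the (n, m) lattice."""
    N = params.N
    lam = params.lam
    grid = np.arange(N + 1) / N
    xA = grid[:, None]  # n axis
    xB = grid[None, :]  # m axis
    piA1, piA2, piB1, piB2 = avg_payoff_2d(bimatrix, (xA, xB))

    def ent(x):
        # -lam*ln(x) with the convention that the result is only used at
        # interior values of the own coordinate (masked below)
        with np.errstate(divide="ignore"):
            return -lam * np.log(x) if lam else np.zeros_like(x)

    fA1 = piA1 + ent(xA)
    fA2 = piA2 + ent(1.0 - xA)
    fB1 = piB1 + ent(xB)
    fB2 = piB2 + ent(1.0 - xB)

    baseA = N * xA * (1.0 - xA) * np.ones_like(xB)
    baseB = N * xB * (1.0 - xB) * np.ones_like(xA)
    with np.errstate(invalid="ignore"):
        aplus = baseA * pairwise_comparison_g(fA1, fA2, params.Gamma)
        aminus = baseA * pairwise_comparison_g(fA2, fA1, params.Gamma)
        bplus = baseB * pairwise_comparison_g(fB1, fB2, params.Gamma)
        bminus = baseB * pairwise_comparison_g(fB2, fB1, params.Gamma)
    # the x(1-x) prefactor vanishes where the fitness diverges; enforce the
    # limit value 0 instead of 0*inf = nan
    for arr in (aplus, aminus):
        arr[0, :] = 0.0
        arr[N, :] = 0.0
    for arr in (bplus, bminus):
        arr[:, 0] = 0.0
        arr[:, N] = 0.0
    rates = TwoPopRates(aplus=aplus, aminus=aminus, bplus=bplus, bminus=bminus, N=N)
    if check:
        diag = validate_rates(rates)
        if not diag.ok:
            raise ValueError(
                f"invalid rates (g outside [0,1]) at states {diag.bad_states[:5]}; "
                f"reduce lam or Gamma (g range [{diag.g_min:.3g}, {diag.g_max:.3g}])"
            )
    return rates


def _g_range_1d(matrix: PayoffMatrix, N: int, Gamma: float, lam: float):
    _, _, f1, f2 = _fitness_1d(matrix, N, lam)
    g = pairwise_comparison_g(f1, f2, Gamma)
    return g, np.concatenate([g, 1.0 - g])


def validate_rates(target, params: Optional[ChainParams] = None) -> RateDiagnostic:
    """Check rate positivity (equivalently g in [0, 1] at every interior state).

    ``target`` is either a built rate object or a game (with ``params``).
    On failure the offending states are reported together with the largest
    admissible lam at the given Gamma (found by bisection, game inputs only).
    """
    lam_max = None
    if isinstance(target, BirthDeathRates1D):
        bad = np.nonzero((target.tplus < 0) | (target.tminus < 0))[0]
        interior = np.arange(1, target.N)
        base = target.N * (interior / target.N) * (1 - interior / target.N)
        g = target.tplus[interior] / base
        return RateDiagnostic(ok=bad.size == 0, bad_states=[int(b) for b in bad],
                              g_min=float(g.min()), g_max=float(g.max()))
    if isinstance(target, TwoPopRates):
        tot_neg = (target.aplus < 0) | (target.aminus < 0) | \
                  (target.bplus < 0) | (target.bminus < 0)
        bad = [(int(n), int(m)) for n, m in np.argwhere(tot_neg)]
        N = target.N
        grid = np.arange(1, N)
        baseA = N * (grid / N) * (1 - grid / N)
        gA = target.aplus[1:N, :] / baseA[:, None]
        gB = target.bplus[:, 1:N] / baseA[None, :]
        gmin = float(min(gA.min(), gB.min()))
        gmax = float(max(gA.max(), gB.max()))
        return RateDiagnostic(ok=len(bad) == 0, bad_states=bad,
                              g_min=gmin, g_max=gmax)

    # game + params input
    game = target
    if params is None:
        raise ValueError("params required when validating a game")

    def ok_at(lam: float) -> tuple:
        p = ChainParams(N=params.N, Gamma=params.Gamma, lam=lam, seed=params.seed)
        if isinstance(game, PayoffBimatrix):
            r = rates_2d(game, p, check=False)
            d = validate_rates(r)
        else:
            r = rates_1d(game, p, check=False)
            d = validate_rates(r)
        return d

    diag = ok_at(params.lam)
    # largest admissible lam at this Gamma by bisection
    lo, hi = 0.0, 1.0
    if ok_at(hi).ok:
        while ok_at(hi).ok and hi < 1e6:
            lo, hi = hi, hi * 2
    if not ok_at(0.0).ok:
        lam_max = 0.0
    else:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if ok_at(mid).ok:
                lo = mid
            else:
                hi = mid
        lam_max = lo
    return RateDiagnostic(ok=diag.ok, bad_states=diag.bad_states,
                          g_min=diag.g_min, g_max=diag.g_max, lam_max=lam_max)


def replicate_seeds(base_seed: int, n_reps: int) -> np.ndarray:
    """Per-replicate seeds derived from one base seed.

    Uses numpy's SeedSequence: child r's seed is generate_state(n_reps)[r],
    so ensembles are reproducible and embarrassingly parallel.
    """
    return np.random.SeedSequence(base_seed).generate_state(n_reps).astype(np.int64)


def gillespie(rates: Union[BirthDeathRates1D, TwoPopRates], init, seed: int,
              t_max: float = math.inf, max_events: int = DEFAULT_MAX_EVENTS,
              record: bool = False) -> Trajectory:
    """Exact stochastic simulation of a validated chain from ``init``.

    ``init`` is an int (1D) or an (n, m) pair (2D); absorbing initial states
    terminate immediately.  With ``record=True`` the full event sequence is
    kept (bounded by max_events, so choose it accordingly).
    """
    seed = int(seed) & 0x7FFFFFFF
    tmax = np.inf if t_max is None else float(t_max)
    if isinstance(rates, BirthDeathRates1D):
        n0 = int(init)
        if not 0 <= n0 <= rates.N:
            raise ValueError(f"init {n0} outside lattice [0, {rates.N}]")
        if record:
            cap = int(min(max_events, 10 ** 7)) + 1
            out_t = np.empty(cap)
            out_n = np.empty(cap, dtype=np.int64)
            n, t, status, k = _kernels.gillespie_1d_record(
                rates.tplus, rates.tminus, n0, seed, tmax, cap - 1, out_t, out_n)
            times, states = out_t[:k], out_n[:k]
            ev = k - 1
        else:
            n, t, status, ev = _kernels.gillespie_1d(
                rates.tplus, rates.tminus, n0, seed, tmax, int(max_events))
            times = states = None
        final = (int(n),)
    else:
        n0, m0 = int(init[0]), int(init[1])
        if not (0 <= n0 <= rates.N and 0 <= m0 <= rates.N):
            raise ValueError(f"init {(n0, m0)} outside lattice")
        if record:
            cap = int(min(max_events, 10 ** 7)) + 1
            out_t = np.empty(cap)
            out_n = np.empty(cap, dtype=np.int64)
            out_m = np.empty(cap, dtype=np.int64)
            n, m, t, status, k = _kernels.gillespie_2d_record(
                rates.aplus, rates.aminus, rates.bplus, rates.bminus,
                n0, m0, seed, tmax, cap - 1, out_t, out_n, out_m)
            times = out_t[:k]
            states = np.stack([out_n[:k], out_m[:k]], axis=1)
            ev = k - 1
        else:
            n, m, t, status, ev = _kernels.gillespie_2d(
                rates.aplus, rates.aminus, rates.bplus, rates.bminus,
                n0, m0, seed, tmax, int(max_events))
            times = states = None
        final = (int(n), int(m))
    absorbed = status == _kernels.ABSORBED
    return Trajectory(
        times=times, states=states,
        absorbed=absorbed,
        censored=status == _kernels.CENSORED,
        hit_tmax=status == _kernels.HIT_TMAX,
        absorption_state=final if absorbed else None,
        absorption_time=float(t) if absorbed else None,
        final_state=final, final_time=float(t), n_events=int(ev),
    )


def run_ensemble(rates, init, n_reps: int, base_seed: int,
                 t_max: float = math.inf,
                 max_events: int = DEFAULT_MAX_EVENTS) -> list:
    """Independent replicate trajectories (seeds via ``replicate_seeds``)."""
    seeds = replicate_seeds(base_seed, n_reps)
    return [gillespie(rates, init, s, t_max=t_max, max_events=max_events)
            for s in seeds]


@dataclass
class TripletCounts:
    """Empirical per-state transition statistics of the triplet microsimulation."""

    visits: np.ndarray   # events initiated at state n
    ups: np.ndarray      # composition-increasing events at n
    downs: np.ndarray
    final_n: int
    n_events: int

    def up_fraction(self):
        with np.errstate(invalid="ignore"):
            return self.ups / self.visits

    def down_fraction(self):
        with np.errstate(invalid="ignore"):
            return self.downs / self.visits


def triplet_microsim(matrix: PayoffMatrix, params: ChainParams, init: int,
                     n_events: int, restart_on_absorption: bool = True
                     ) -> TripletCounts:
    """Microscopic triplet-sampling realisation of the payoff-based chain.

    Defined for lam = 0 only: the entropic fitness term is a population-level
    quantity with no per-encounter payoff interpretation, so there is no
    triplet-level construction for it.  Per event an ordered (primary,
    secondary, adversary) triplet is drawn with replacement; both play the
    adversary and the secondary switches to the primary's type with the
    pairwise comparison probability of their realised payoffs.  Averaging
    over the adversary reproduces the birth-death rates exactly.
    """
    if params.lam != 0:
        raise ValueError("triplet_microsim is defined for lam = 0 only")
    if not 0 <= init <= params.N:
        raise ValueError("init outside lattice")
    # per-event acceptance must be a probability for every payoff pair
    if params.Gamma * float(np.ptp(matrix.array)) > 1.0:
        raise ValueError("Gamma too large: per-encounter g outside [0, 1]")
    visits, ups, downs, n = _kernels.triplet_sim(
        matrix.a11, matrix.a12, matrix.a21, matrix.a22,
        params.N, params.Gamma, int(init), int(n_events),
        int(params.seed) & 0x7FFFFFFF, restart_on_absorption)
    return TripletCounts(visits=visits, ups=ups, downs=downs,
                         final_n=int(n), n_events=int(n_events))
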