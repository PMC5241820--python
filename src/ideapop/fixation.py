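"""Fixation probabilities and mean fixation times.

Three routes to the same quantities, used as mutual cross-checks:

* closed-form birth-death sums (1D only), evaluated in log space so the
  running products of T-/T+ ratios never overflow even for strong selection;
* the backward master equation, solved as a sparse linear system for the
  unconditional mean absorption time tau(state) with tau = 0 at absorbing
  states (1D tridiagonal; 2D on the (N+1)^2 lattice minus the four corners);
* Monte-Carlo statistics over Gillespie replicate ensembles.

All times are unconditional means over the absorbing boundaries, in
generations.  Scaling-law fits (power law, exponential, logarithmic in N)
characterise the three fixation mechanisms: diffusive drift-free wandering
(tau ~ N), activation against a restoring flow (tau ~ e^{cN}), and
deterministic relaxation (tau ~ ln N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.stats import linregress

from . import _kernels
from .dynamics import DynParams, integrate_flow, make_flow_1d
from .games import PayoffBimatrix, PayoffMatrix
from .stochastic import (BirthDeathRates1D, ChainParams, Trajectory,
                         TwoPopRates, rates_2d, replicate_seeds)

__all__ = [
    "FixationResult",
    "ScalingFit",
    "fixation_closed_form_1d",
    "fixation_linear_solve",
    "mc_fixation_stats",
    "fit_scaling",
    "compare_scaling_models",
    "diffusion_exponent",
    "relaxation_time",
]


@dataclass
class FixationResult:
    mean_time: float                     # tau at the requested start (generations)
    tau: np.ndarray                      # tau per state: (N+1,) or (N+1, N+1)
    method: str                          # closed_form | linear_solve | monte_carlo
    fixation_prob_upper: Optional[float] = None   # P(absorb at n = N), 1D
    se: Optional[float] = None           # standard error (monte_carlo)
    n_censored: int = 0
    absorption_distribution: Optional[dict] = None


@dataclass
class ScalingFit:
    model: str                  # power_law | exponential | logarithmic
    slope: float                # exponent (power_law), rate (exponential) or prefactor
    stderr: float
    intercept: float
    r_squared: float
    window: tuple               # (x_min, x_max) actually used
    n_points: int


# ---------------------------------------------------------------------------
# exact 1D closed form

def _log_cumsum_exp(logs: np.ndarray) -> np.ndarray:
    return np.logaddexp.accumulate(logs)


def fixation_closed_form_1d(rates: BirthDeathRates1D, n0: int) -> FixationResult:
    """Standard birth-death sums for absorption probability and mean time.

    With gamma_k = T-_k / T+_k and rho_k = prod_{j<=k} gamma_j (rho_0 = 1):

        P(absorb at N | n)  = sum_{k<n} rho_k / sum_{k<N} rho_k
        tau_{n+1} - tau_n   = rho_n * (d_0 - C_n),   C_n = sum_{l<=n} 1/(rho_l T+_l)

    with d_0 fixed by tau_N = 0.  All products and sums of positive terms are
    kept in log space.
    """
    N = rates.N
    if not 0 <= n0 <= N:
        raise ValueError("n0 outside lattice")
    tp = rates.tplus[1:N]
    tm = rates.tminus[1:N]
    if np.any(tp <= 0) or np.any(tm < 0):
        raise ValueError("closed form requires positive interior birth rates")
    log_gamma = np.log(tm) - np.log(tp)
    log_rho = np.concatenate([[0.0], np.cumsum(log_gamma)])      # k = 0..N-1
    log_cum_rho = _log_cumsum_exp(log_rho)                       # log sum_{k<=j} rho_k
    log_S1 = log_cum_rho[-1]
    # fixation probabilities at every n
    prob = np.zeros(N + 1)
    prob[1:N] = np.exp(log_cum_rho[:-1][np.arange(1, N) - 1] - log_S1)
    prob[N] = 1.0

    # C_k = sum_{l=1}^{k} 1/(rho_l T+_l), k = 1..N-1, in log space
    log_terms = -(log_rho[1:] + np.log(tp))                      # l = 1..N-1
    log_C = _log_cumsum_exp(log_terms)                           # k = 1..N-1
    # d_0 = sum_{k=1}^{N-1} rho_k C_k / sum_{k=0}^{N-1} rho_k
    log_num_terms = log_rho[1:] + log_C
    log_S2 = log_num_terms[0] if log_num_terms.size == 1 else \
        np.logaddexp.reduce(log_num_terms)
    log_d0 = log_S2 - log_S1

    # d_k = rho_k * (d_0 - C_k); signed evaluation in log space
    d = np.empty(N)                                              # k = 0..N-1
    d[0] = math.exp(log_d0)
    diff = log_d0 - log_C                                        # k = 1..N-1
    mag = log_rho[1:] + np.maximum(log_d0, log_C) + np.log1p(-np.exp(-np.abs(diff)))
    sign = np.sign(diff)
    with np.errstate(over="ignore"):
        d[1:] = sign * np.exp(mag)
    d[1:][diff == 0.0] = 0.0
    tau = np.concatenate([[0.0], np.cumsum(d)])
    tau[N] = 0.0  # exact boundary condition (cumsum closes to 0 up to roundoff)
    return FixationResult(mean_time=float(tau[n0]), tau=tau, method="closed_form",
                          fixation_prob_upper=float(prob[n0]))


# ---------------------------------------------------------------------------
# backward master equation

def _solve_1d(rates: BirthDeathRates1D) -> np.ndarray:
    N = rates.N
    idx = np.arange(1, N)
    tp = rates.tplus[idx]
    tm = rates.tminus[idx]
    main = -(tp + tm)
    A = sparse.diags([tm[1:], main, tp[:-1]], offsets=[-1, 0, 1], format="csc")
    tau_int = spsolve(A, -np.ones(N - 1))
    tau = np.zeros(N + 1)
    tau[1:N] = tau_int
    return tau


def _solve_2d(rates: TwoPopRates) -> np.ndarray:
    N = rates.N
    n_states = (N + 1) ** 2
    corner_ids = {0, N, N * (N + 1), N * (N + 1) + N}

    def sid(n, m):
        return n * (N + 1) + m

    transient = np.array([s for s in range(n_states) if s not in corner_ids])
    col_of = -np.ones(n_states, dtype=np.int64)
    col_of[transient] = np.arange(transient.size)

    rows, cols, vals = [], [], []
    rhs = -np.ones(transient.size)
    for k, s in enumerate(transient):
        n, m = divmod(s, N + 1)
        total = 0.0
        for rate, dn, dm in ((rates.aplus[n, m], 1, 0), (rates.aminus[n, m], -1, 0),
                             (rates.bplus[n, m], 0, 1), (rates.bminus[n, m], 0, -1)):
            if rate <= 0.0:
                continue
            total += rate
            t = sid(n + dn, m + dm)
            if col_of[t] >= 0:
                rows.append(k)
                cols.append(col_of[t])
                vals.append(rate)
        if total <= 0.0:
            raise ValueError(f"state {(n, m)} is absorbing but not a corner")
        rows.append(k)
        cols.append(k)
        vals.append(-total)
    A = sparse.csc_matrix((vals, (rows, cols)),
                          shape=(transient.size, transient.size))
    tau_t = spsolve(A, rhs)
    if not np.all(np.isfinite(tau_t)):
        raise ValueError("singular backward system: disconnected transient states")
    tau = np.zeros(n_states)
    tau[transient] = tau_t
    return tau.reshape(N + 1, N + 1)


def fixation_linear_solve(rates: Union[BirthDeathRates1D, TwoPopRates],
                          init=None) -> FixationResult:
    """Unconditional mean absorption times from the backward master equation.

    Solves sum_r T_r(s) [tau(s_r) - tau(s)] = -1 over all transient states
    with tau = 0 imposed at the absorbing states; sparse direct solve.
    """
    if isinstance(rates, BirthDeathRates1D):
        tau = _solve_1d(rates)
        mean = float(tau[int(init)]) if init is not None else float(np.max(tau))
        prob = None
        if init is not None:
            # fixation probability by the same backward operator, rhs 0
            N = rates.N
            idx = np.arange(1, N)
            tp = rates.tplus[idx]
            tm = rates.tminus[idx]
            A = sparse.diags([tm[1:], -(tp + tm), tp[:-1]],
                             offsets=[-1, 0, 1], format="csc")
            rhs = np.zeros(N - 1)
            rhs[-1] = -tp[-1]      # phi(N) = 1 boundary term
            phi = spsolve(A, rhs)
            prob = float(phi[int(init) - 1]) if 0 < int(init) < N \
                else float(int(init) == N)
        return FixationResult(mean_time=mean, tau=tau, method="linear_solve",
                              fixation_prob_upper=prob)
    tau = _solve_2d(rates)
    mean = float(tau[int(init[0]), int(init[1])]) if init is not None \
        else float(np.max(tau))
    return FixationResult(mean_time=mean, tau=tau, method="linear_solve")


# ---------------------------------------------------------------------------
# Monte Carlo

def mc_fixation_stats(ensemble: Sequence[Trajectory]) -> FixationResult:
    """Ensemble mean fixation time, standard error and absorption distribution.

    Censored replicates (max_events) and t_max-truncated replicates are
    excluded from the mean and reported via ``n_censored``.
    """
    times = np.array([tr.absorption_time for tr in ensemble if tr.absorbed])
    n_censored = sum(1 for tr in ensemble if not tr.absorbed)
    if times.size == 0:
        raise ValueError("all replicates censored: no absorption observed")
    dist: dict = {}
    for tr in ensemble:
        if tr.absorbed:
            dist[tr.absorption_state] = dist.get(tr.absorption_state, 0) + 1
    se = float(times.std(ddof=1) / math.sqrt(times.size)) if times.size > 1 else 0.0
    return FixationResult(mean_time=float(times.mean()), tau=times,
                          method="monte_carlo", se=se, n_censored=n_censored,
                          absorption_distribution=dist)


# ---------------------------------------------------------------------------
# scaling laws

_MODELS = ("power_law", "exponential", "logarithmic")


def fit_scaling(xs: Sequence[float], taus: Sequence[float],
                model: str = "power_law") -> ScalingFit:
    """Least-squares fit of a scaling law tau(x).

    power_law: log tau ~ slope * log x; exponential: log tau ~ slope * x;
    logarithmic: tau ~ slope * log x.  Returns the slope with its standard
    error and the R^2 of the model's own linearisation.
    """
    xs = np.asarray(xs, dtype=float)
    taus = np.asarray(taus, dtype=float)
    if xs.size < 4:
        raise ValueError("need >= 4 points for a scaling fit")
    if np.any(taus <= 0):
        raise ValueError("scaling fit requires positive times")
    if model == "power_law":
        u, v = np.log(xs), np.log(taus)
    elif model == "exponential":
        u, v = xs, np.log(taus)
    elif model == "logarithmic":
        u, v = np.log(xs), taus
    else:
        raise ValueError(f"unknown model {model!r}; choose from {_MODELS}")
    res = linregress(u, v)
    return ScalingFit(model=model, slope=float(res.slope),
                      stderr=float(res.stderr), intercept=float(res.intercept),
                      r_squared=float(res.rvalue ** 2),
                      window=(float(xs.min()), float(xs.max())),
                      n_points=int(xs.size))


def compare_scaling_models(xs, taus, models=_MODELS) -> dict:
    """Fit several scaling models side by side (keyed by model name)."""
    return {m: fit_scaling(xs, taus, m) for m in models}


# ---------------------------------------------------------------------------
# diffusive exponent (two-population, drift-free regime)

def diffusion_exponent(bimatrix: PayoffBimatrix, params: ChainParams,
                       n_reps: int = 200, t_end: Optional[float] = None,
                       n_samples: int = 80, d_min: Optional[float] = None,
                       d_max: float = 0.25, min_points: int = 10):
    """Growth exponent of the RMS distance from the central fixed point.

    Simulates ``n_reps`` chains from (N/2, N/2), records the state at
    log-spaced sample times, and fits log RMS-d against log t over the
    automatic window d in [2/N, 0.25] (pre-saturation).  For a drift-free
    (cyclic, lam = 0) game the radial motion is purely diffusive and the
    exponent is 1/2.

    Returns (fit, times, rms_d).
    """
    N = params.N
    if N % 2:
        raise ValueError("use even N so (N/2, N/2) is a lattice state")
    d_min = 2.0 / N if d_min is None else d_min
    rates = rates_2d(bimatrix, params)
    t_end = 3.0 * N if t_end is None else t_end
    sample_times = np.logspace(math.log10(0.05), math.log10(t_end), n_samples)
    seeds = replicate_seeds(params.seed, n_reps)
    d2 = np.zeros((n_reps, n_samples))
    out_n = np.empty(n_samples, dtype=np.int64)
    out_m = np.empty(n_samples, dtype=np.int64)
    for r, s in enumerate(seeds):
        _kernels.gillespie_2d_sampled(
            rates.aplus, rates.aminus, rates.bplus, rates.bminus,
            N // 2, N // 2, int(s) & 0x7FFFFFFF, sample_times,
            10 ** 9, out_n, out_m)
        d2[r] = (out_n / N - 0.5) ** 2 + (out_m / N - 0.5) ** 2
    rms = np.sqrt(d2.mean(axis=0))
    # the window must describe genuine growth: it runs from the first crossing
    # of d_min to the first crossing of d_max.  If the RMS distance never
    # reaches d_max the motion has saturated at a metastable plateau (e.g.
    # fluctuation around an interior attractor) and no diffusive window exists.
    above = np.nonzero(rms >= d_max)[0]
    if above.size == 0:
        raise ValueError(
            "no valid scaling window: RMS distance saturates below d_max "
            "(metastable plateau instead of diffusive growth)")
    lo = np.nonzero(rms >= d_min)[0][0]
    mask = np.zeros_like(rms, dtype=bool)
    mask[lo:above[0] + 1] = True
    mask &= rms > 0
    if mask.sum() < min_points:
        raise ValueError(
            f"scaling window too short ({int(mask.sum())} points, "
            f"need {min_points})")
    res = linregress(np.log(sample_times[mask]), np.log(rms[mask]))
    fit = ScalingFit(model="power_law", slope=float(res.slope),
                     stderr=float(res.stderr), intercept=float(res.intercept),
                     r_squared=float(res.rvalue ** 2),
                     window=(float(sample_times[mask].min()),
                             float(sample_times[mask].max())),
                     n_points=int(mask.sum()))
    return fit, sample_times, rms


# ---------------------------------------------------------------------------
# deterministic relaxation time (lattice-resolution cutoff)

def relaxation_time(game: PayoffMatrix, params: DynParams, x0: float,
                    x_star: float, N: int, c: float = 1.0,
                    t_cap: float = 1e5) -> float:
    """Time for the deterministic flow to reach within c/N of a fixed point.

    The order-unity constant ``c`` sets the lattice-resolution cutoff used to
    compare deterministic relaxation with finite-population fixation.
    """
    flow = make_flow_1d(game, params)
    target = c / N
    traj = integrate_flow(flow, x0, t_cap, n_out=4096)
    dist = np.abs(traj.states - x_star)
    hit = np.nonzero(dist <= target)[0]
    if hit.size == 0:
        raise ValueError("flow did not reach the fixed point within t_cap")
    k = hit[0]
    if k == 0:
        return 0.0
    # linear interpolation in log-distance between the bracketing samples
    t0, t1 = traj.times[k - 1], traj.times[k]
    d0, d1 = dist[k - 1], dist[k]
    if d0 <= 0 or d1 <= 0 or d0 == d1:
        return float(t1)
    w = (math.log(d0) - math.log(target)) / (math.log(d0) - math.log(d1))
    return float(t0 + w * (t1 - t0))
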