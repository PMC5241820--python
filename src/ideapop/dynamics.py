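"""Deterministic flows: replicator, Sato-Crutchfield, replicator-mutator.

The Sato-Crutchfield equations are the infinite-population / continuous-time
limit of reinforcement learning with memory loss.  For a two-strategy game
they reduce to a replicator flow with an *entropically modified* fitness

    f_i = pi_i - lam * ln(x_i),

so the one-population flow reads

    dx/dt = Gamma * x * (1 - x) * (f_1 - f_2)
          = Gamma * x * (1 - x) * (pi_1 - pi_2 - lam * ln(x / (1 - x))).

``Gamma`` is the intensity of choice (selection strength), ``lam`` the memory
loss strength: the log term is an entropic restoring force toward the
uniformly mixed strategy x = 1/2.  The boundary points x = 0, 1 are fixed
points for every game and every lam (the x(1-x) prefactor dominates the log
divergence), but for lam > 0 they are always repelling, so any attractor lies
in the interior.

The two-population version couples two such flows through the opponent's
mixed strategy; the replicator-mutator flow replaces the entropic force by a
symmetric mutation flux u*(1 - 2x), which removes the boundary fixed points
altogether.

This module also provides numerical fixed-point location/classification and
bifurcation scans over lam (saddle-node detection by fixed-point count).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .games import PayoffBimatrix, PayoffMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DynParams",
    "FixedPoint",
    "FixedPointSet",
    "BifurcationResult",
    "FlowTrajectory",
    "avg_payoff_1d",
    "avg_payoff_2d",
    "modified_fitness",
    "sc_flow_1d",
    "sc_flow_2d",
    "replicator_flow_1d",
    "replicator_mutator_flow",
    "make_flow_1d",
    "make_flow_2d",
    "integrate_flow",
    "find_fixed_points",
    "bifurcation_scan",
]

# numerical policy (see docs/methods.md)
ROOT_TOL = 1e-10          # |flow| at an accepted root
DEDUP_TOL = 1e-6          # min separation between reported fixed points
EIG_TOL = 1e-8            # |Re(eig)| below this + Im != 0 -> center
BOUNDARY_PROBE = 1e-13    # inward offset used to classify boundary points
LAMC_TOL = 1e-4           # bisection width for saddle-node locations


@dataclass(frozen=True)
class DynParams:
    """Deterministic-flow parameters.

    Gamma: intensity of choice (>= 0); lam: memory-loss strength (>= 0);
    u: mutation rate (>= 0, replicator-mutator mode only).
    """

    Gamma: float = 0.1
    lam: float = 0.0
    u: float = 0.0

    def __post_init__(self) -> None:
        if self.Gamma < 0 or self.lam < 0 or self.u < 0:
            raise ValueError("Gamma, lam and u must all be >= 0")


@dataclass(frozen=True)
class FixedPoint:
    location: tuple  # (x,) in 1D, (xA, xB) in 2D
    stability: str   # stable | saddle | unstable | center
    eigenvalues: tuple  # real scalar (1D) or complex pair (2D); nan if divergent


@dataclass
class FixedPointSet:
    points: list
    tol: float = ROOT_TOL

    def __iter__(self):
        return iter(self.points)

    def __len__(self):
        return len(self.points)

    def interior(self, eps: float = 0.0) -> list:
        return [
            p for p in self.points
            if all(eps < c < 1 - eps for c in p.location)
        ]

    def stable(self) -> list:
        return [p for p in self.points if p.stability == "stable"]


@dataclass
class BifurcationResult:
    lam_grid: np.ndarray
    counts: np.ndarray                 # fixed-point count per lam
    branches: list                     # FixedPointSet per lam
    lam_c: list = field(default_factory=list)   # refined bifurcation values
    lam_c_bracket: list = field(default_factory=list)


@dataclass
class FlowTrajectory:
    times: np.ndarray
    states: np.ndarray   # shape (n_times,) in 1D, (n_times, 2) in 2D
    sol: object = None   # dense-output interpolant from the integrator


# ---------------------------------------------------------------------------
# payoffs and fitness

def avg_payoff_1d(matrix: PayoffMatrix, x) -> tuple:
    """Average payoffs (pi1, pi2) at composition x (fraction of type 1).

    pi_i = a_i1 * x + a_i2 * (1 - x).  Evaluated at x = n/N this is the
    finite-population fitness pi_1 = [a11*n + a12*(N-n)] / N.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x must lie in [0, 1]")
    pi1 = matrix.a11 * x + matrix.a12 * (1.0 - x)
    pi2 = matrix.a21 * x + matrix.a22 * (1.0 - x)
    return pi1, pi2


def avg_payoff_2d(bimatrix: PayoffBimatrix, state) -> tuple:
    """Average payoffs (piA1, piA2, piB1, piB2) at state (xA, xB).

    Each player's payoff is linear in the *other* player's mixed strategy:
    piA_i = a_i1 * xB + a_i2 * (1 - xB), piB_i = b_i1 * xA + b_i2 * (1 - xA).
    """
    xA, xB = state
    xA = np.asarray(xA, dtype=float)
    xB = np.asarray(xB, dtype=float)
    if np.any((xA < 0) | (xA > 1)) or np.any((xB < 0) | (xB > 1)):
        raise ValueError("state components must lie in [0, 1]")
    a, b = bimatrix.A, bimatrix.B
    piA1 = a.a11 * xB + a.a12 * (1.0 - xB)
    piA2 = a.a21 * xB + a.a22 * (1.0 - xB)
    piB1 = b.a11 * xA + b.a12 * (1.0 - xA)
    piB2 = b.a21 * xA + b.a22 * (1.0 - xA)
    return piA1, piA2, piB1, piB2


def modified_fitness(pi_i, x_i, lam: float):
    """Entropically modified fitness f_i = pi_i - lam * ln(x_i).

    Frequent types are penalised, rare types favoured; lam = 0 recovers the
    plain payoff.  Divergent at x_i = 0 when lam > 0: callers must never
    evaluate the fitness of an extinct type.
    """
    x_i = np.asarray(x_i, dtype=float)
    if lam == 0:
        return np.asarray(pi_i, dtype=float) + 0.0 * x_i
    if np.any(x_i <= 0):
        raise ValueError("modified fitness diverges at x_i = 0 for lam > 0")
    return pi_i - lam * np.log(x_i)


# ---------------------------------------------------------------------------
# flows

def _fitness_gap_1d(matrix: PayoffMatrix, x, lam: float):
    """f1 - f2 at interior x (vectorised; assumes 0 < x < 1)."""
    pi1, pi2 = avg_payoff_1d(matrix, x)
    if lam == 0:
        return pi1 - pi2
    return pi1 - pi2 - lam * (np.log(x) - np.log1p(-x))


def sc_flow_1d(matrix: PayoffMatrix, x, params: DynParams):
    """Single-population Sato-Crutchfield velocity dx/dt.

    Gamma * x * (1-x) * (f1 - f2); exactly 0 at x = 0 and x = 1 (limit value).
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x must lie in [0, 1]")
    out = np.zeros_like(x)
    inner = (x > 0) & (x < 1)
    xi = x[inner]
    out[inner] = params.Gamma * xi * (1.0 - xi) * _fitness_gap_1d(matrix, xi, params.lam)
    return float(out[0]) if scalar else out


def replicator_flow_1d(matrix: PayoffMatrix, x):
    """Plain two-type replicator velocity x(1-x)(pi1 - pi2) (no Gamma)."""
    x = np.asarray(x, dtype=float)
    pi1, pi2 = avg_payoff_1d(matrix, x)
    return x * (1.0 - x) * (pi1 - pi2)


def sc_flow_2d(bimatrix: PayoffBimatrix, state, params: DynParams) -> tuple:
    """Two-population Sato-Crutchfield velocities (dxA/dt, dxB/dt).

    Each component has the one-population form in its own coordinate, with
    payoffs evaluated against the other population's strategy.
    """
    xA, xB = (float(state[0]), float(state[1]))
    piA1, piA2, piB1, piB2 = avg_payoff_2d(bimatrix, (xA, xB))

    def comp(x, dpi):
        if x <= 0.0 or x >= 1.0:
            return 0.0
        gap = dpi if params.lam == 0 else dpi - params.lam * (math.log(x) - math.log1p(-x))
        return params.Gamma * x * (1.0 - x) * gap

    return comp(xA, float(piA1 - piA2)), comp(xB, float(piB1 - piB2))


def replicator_mutator_flow(matrix: PayoffMatrix, x, params: DynParams):
    """Replicator-mutator velocity Gamma*x(1-x)(pi1-pi2) + u*(1-2x).

    The symmetric mutation flux u*(1-2x) pushes toward x = 1/2 and makes the
    boundary non-absorbing: the flow at x = 0 is +u, at x = 1 it is -u.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x must lie in [0, 1]")
    pi1, pi2 = avg_payoff_1d(matrix, x)
    val = params.Gamma * x * (1.0 - x) * (pi1 - pi2) + params.u * (1.0 - 2.0 * x)
    return float(val) if val.ndim == 0 else val


def make_flow_1d(game: PayoffMatrix, params: DynParams,
                 kind: str = "sato_crutchfield") -> Callable:
    """Return a scalar flow callable x -> dx/dt for the given game/parameters."""
    if kind == "sato_crutchfield":
        return lambda x: sc_flow_1d(game, x, params)
    if kind == "replicator_mutator":
        return lambda x: replicator_mutator_flow(game, x, params)
    if kind == "replicator":
        return lambda x: replicator_flow_1d(game, x)
    raise ValueError(f"unknown flow kind {kind!r}")


def make_flow_2d(game: PayoffBimatrix, params: DynParams) -> Callable:
    """Return a flow callable (xA, xB) -> (dxA/dt, dxB/dt)."""
    return lambda s: sc_flow_2d(game, s, params)


# ---------------------------------------------------------------------------
# integration

def integrate_flow(flow: Callable, x0, t_end: float,
                   rel_tol: float = 1e-9, abs_tol: float = 1e-9,
                   n_out: int = 512) -> FlowTrajectory:
    """Integrate an autonomous flow with a stiff-capable adaptive scheme.

    ``flow`` maps a state (scalar or pair) to its velocity.  States are
    clipped to [0, 1] only within abs_tol of the boundary.
    """
    x0_arr = np.atleast_1d(np.asarray(x0, dtype=float))
    dim = x0_arr.size

    def rhs(_t, y):
        yc = np.clip(y, 0.0, 1.0)
        v = flow(float(yc[0])) if dim == 1 else flow((yc[0], yc[1]))
        return np.atleast_1d(np.asarray(v, dtype=float))

    sol = solve_ivp(rhs, (0.0, float(t_end)), x0_arr, method="LSODA",
                    rtol=rel_tol, atol=abs_tol, dense_output=True,
                    t_eval=np.linspace(0.0, float(t_end), n_out))
    if not sol.success:
        raise RuntimeError(f"flow integration failed: {sol.message}")
    states = sol.y.T
    # clip roundoff excursions just outside the simplex
    states = np.clip(states, -abs_tol, 1.0 + abs_tol)
    states = np.clip(states, 0.0, 1.0)
    return FlowTrajectory(times=sol.t,
                          states=states[:, 0] if dim == 1 else states,
                          sol=sol.sol)


# ---------------------------------------------------------------------------
# fixed points

def _near_boundary_grid(n_grid: int) -> np.ndarray:
    """Uniform grid on (0,1) augmented with log-spaced points near 0 and 1.

    Interior fixed points can sit exponentially close to the boundary (at
    distance ~exp(-c/lam)); a uniform grid would miss the sign change.
    """
    uni = np.linspace(0.0, 1.0, max(int(n_grid), 64))
    lo = np.logspace(-14, -1.5, 48)
    return np.unique(np.concatenate([uni, lo, 1.0 - lo]))


def _classify_1d(flow: Callable, x: float, neighbours: Sequence[float]) -> FixedPoint:
    """Classify a 1D root by flow signs on either side (robust near boundaries)."""
    lo_gap = min([x - nb for nb in neighbours if nb < x], default=x)
    hi_gap = min([nb - x for nb in neighbours if nb > x], default=1.0 - x)
    if x <= 0.0:
        s_right = math.copysign(1.0, flow(min(BOUNDARY_PROBE, hi_gap / 2) or BOUNDARY_PROBE))
        label = "unstable" if s_right > 0 else "stable"
        eig = math.nan
    elif x >= 1.0:
        s_left = math.copysign(1.0, flow(1.0 - (min(BOUNDARY_PROBE, lo_gap / 2) or BOUNDARY_PROBE)))
        label = "unstable" if s_left < 0 else "stable"
        eig = math.nan
    else:
        dl = min(lo_gap / 2, x / 2, 1e-4)
        dr = min(hi_gap / 2, (1.0 - x) / 2, 1e-4)
        fl, fr = flow(x - dl), flow(x + dr)
        if fl > 0 and fr < 0:
            label = "stable"
        elif fl < 0 and fr > 0:
            label = "unstable"
        else:  # degenerate (semi-stable); report as saddle-like
            label = "saddle"
        h = min(dl, dr)
        eig = (flow(x + h) - flow(x - h)) / (2 * h)
    return FixedPoint(location=(float(x),), stability=label, eigenvalues=(eig,))


def _find_fixed_points_1d(flow: Callable, n_grid: int, tol: float) -> FixedPointSet:
    grid = _near_boundary_grid(n_grid)
    vals = np.array([flow(g) for g in grid])
    # the boundaries are always tested; they are fixed points of every
    # entropic-replicator flow but not, e.g., of the replicator-mutator flow
    boundary = [b for b in (0.0, 1.0) if abs(flow(b)) <= max(tol, 1e-12)]
    roots = list(boundary)
    for i in range(len(grid) - 1):
        a, b = grid[i], grid[i + 1]
        fa, fb = vals[i], vals[i + 1]
        if a == 0.0 or b == 1.0:
            # skip brackets that touch the exact boundary zeros
            if fa == 0.0 or fb == 0.0:
                continue
        if fa == 0.0 and a not in (0.0, 1.0):
            roots.append(a)
            continue
        if fa * fb < 0:
            try:
                r = brentq(flow, a, b, xtol=1e-15, rtol=8.9e-16)
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("root refinement failed in [%g, %g]: %s", a, b, exc)
                continue
            roots.append(float(r))
    # Deduplicate interior roots at DEDUP_TOL separation.  The exact boundary
    # points are kept regardless: an interior root may legitimately sit closer
    # than DEDUP_TOL to the boundary (at distance ~exp(-c/lam)) and is still a
    # distinct fixed point as long as it is representable in float64.
    interior = sorted(r for r in roots if 1e-15 < r < 1.0 - 1e-15
                      and abs(flow(r)) <= max(tol, 1e-12))
    dedup: list[float] = []
    for r in interior:
        if not dedup or r - dedup[-1] > DEDUP_TOL:
            dedup.append(r)
    final = sorted(boundary + dedup)
    pts = [_classify_1d(flow, r, [q for q in final if q != r]) for r in final]
    return FixedPointSet(points=pts, tol=tol)


def _jacobian_2d(flow: Callable, s: tuple, h: float = 1e-6) -> np.ndarray:
    J = np.empty((2, 2))
    for j in range(2):
        sp = list(s)
        sm = list(s)
        hj = min(h, (1.0 - s[j]) / 2, s[j] / 2) or h
        sp[j] += hj
        sm[j] -= hj
        fp = np.asarray(flow(tuple(sp)), dtype=float)
        fm = np.asarray(flow(tuple(sm)), dtype=float)
        J[:, j] = (fp - fm) / (2 * hj)
    return J


def _classify_2d_interior(flow: Callable, s: tuple) -> FixedPoint:
    eig = np.linalg.eigvals(_jacobian_2d(flow, s))
    re, im = eig.real, eig.imag
    if np.all(np.abs(re) < EIG_TOL) and np.all(np.abs(im) > EIG_TOL):
        label = "center"
    elif np.all(re < -EIG_TOL):
        label = "stable"
    elif np.all(re > EIG_TOL):
        label = "unstable"
    elif re.min() < -EIG_TOL < EIG_TOL < re.max():
        label = "saddle"
    else:  # marginal along one direction
        label = "saddle"
    return FixedPoint(location=(float(s[0]), float(s[1])), stability=label,
                      eigenvalues=(complex(eig[0]), complex(eig[1])))


def _classify_2d_boundary(flow: Callable, s: tuple) -> FixedPoint:
    """Classify corner/edge fixed points by probing flow signs just inside.

    The entropic term makes the Jacobian divergent on the boundary, so
    derivative-based classification is replaced by directional sign probes.
    """
    xA, xB = s
    d = BOUNDARY_PROBE
    signs = []
    for axis, x in enumerate((xA, xB)):
        if x <= 0.0:
            probe = list(s)
            probe[axis] = d
            v = flow((probe[0], probe[1]))[axis]
            signs.append("out" if v > 0 else "in")   # out = repelling from boundary
        elif x >= 1.0:
            probe = list(s)
            probe[axis] = 1.0 - d
            v = flow((probe[0], probe[1]))[axis]
            signs.append("out" if v < 0 else "in")
        else:
            # tangential direction of an edge point: probe both sides
            lo = list(s)
            hi = list(s)
            step = min(1e-7, x / 2, (1 - x) / 2)
            lo[axis] -= step
            hi[axis] += step
            vl = flow((lo[0], lo[1]))[axis]
            vh = flow((hi[0], hi[1]))[axis]
            if vl > 0 and vh < 0:
                signs.append("in")
            elif vl < 0 and vh > 0:
                signs.append("out")
            else:
                signs.append("out")  # semi-stable tangentially: not attracting
    n_out = signs.count("out")
    label = "stable" if n_out == 0 else ("unstable" if n_out == 2 else "saddle")
    return FixedPoint(location=(float(xA), float(xB)), stability=label,
                      eigenvalues=(math.nan, math.nan))


def _find_fixed_points_2d(flow: Callable, n_grid: int, tol: float) -> FixedPointSet:
    pts: list[FixedPoint] = []
    found: list[tuple] = []

    def register(s, boundary: bool):
        for f in found:
            if abs(f[0] - s[0]) < DEDUP_TOL and abs(f[1] - s[1]) < DEDUP_TOL:
                return
        found.append(s)
        pts.append(_classify_2d_boundary(flow, s) if boundary
                   else _classify_2d_interior(flow, s))

    # corners are always fixed points
    for c in ((0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)):
        register(c, boundary=True)

    # edge fixed points: 1D root-finding along each face with the other
    # coordinate frozen at 0 or 1
    axis_grid = _near_boundary_grid(max(n_grid, 64))
    interior_axis = axis_grid[(axis_grid > 0) & (axis_grid < 1)]
    for axis in (0, 1):
        for fixed_val in (0.0, 1.0):
            def edge_flow(x, axis=axis, fv=fixed_val):
                s = [fv, fv]
                s[axis] = x
                return flow((s[0], s[1]))[axis]
            vals = np.array([edge_flow(x) for x in interior_axis])
            for i in range(len(interior_axis) - 1):
                if vals[i] == 0.0:
                    r = interior_axis[i]
                elif vals[i] * vals[i + 1] < 0:
                    r = brentq(edge_flow, interior_axis[i], interior_axis[i + 1],
                               xtol=1e-15, rtol=8.9e-16)
                else:
                    continue
                s = [fixed_val, fixed_val]
                s[axis] = float(r)
                register(tuple(s), boundary=True)

    # interior: grid seeds (uniform + near-corner log-spaced along diagonals)
    # refined with a multidimensional root solve
    n_side = max(int(math.isqrt(max(n_grid, 64))), 12)
    uni = np.linspace(0.05, 0.95, n_side)
    seeds = [(a, b) for a in uni for b in uni]
    eps_list = np.logspace(-9, -1.2, 12)
    for e in eps_list:
        seeds.extend([(e, e), (1 - e, 1 - e), (e, 1 - e), (1 - e, e)])

    def vec_flow(v):
        # hybr may probe outside the unit square; evaluate at the clipped
        # point and add the excursion so such probes never look like roots
        vc = np.clip(v, 1e-16, 1.0 - 1e-16)
        return np.asarray(flow((vc[0], vc[1])), dtype=float) + (v - vc)

    for s0 in seeds:
        sol = root(vec_flow, np.asarray(s0, dtype=float), method="hybr",
                   options={"xtol": 1e-13})
        if not sol.success:
            continue
        s = sol.x
        if not (0 < s[0] < 1 and 0 < s[1] < 1):
            continue
        if np.max(np.abs(vec_flow(s))) > max(tol, 1e-11):
            continue
        register((float(s[0]), float(s[1])), boundary=False)

    pts.sort(key=lambda p: p.location)
    return FixedPointSet(points=pts, tol=tol)


def find_fixed_points(flow: Callable, domain="1d", n_grid: int = 256,
                      tol: float = ROOT_TOL) -> FixedPointSet:
    """Locate and classify all fixed points of a flow on [0,1] or [0,1]^2.

    ``domain`` is "1d"/"2d" (or a 1- vs 2-interval domain tuple).  1D: sign
    changes on a boundary-refined grid + Brent refinement, boundaries always
    included.  2D: corners + per-edge 1D searches + interior grid-seeded
    multidimensional root refinement with deduplication.
    """
    if n_grid < 64:
        raise ValueError("n_grid must be >= 64")
    dim = 2 if (domain == "2d" or (not isinstance(domain, str) and len(domain) == 2
                                   and np.ndim(domain[0]) > 0)) else 1
    if dim == 1:
        return _find_fixed_points_1d(flow, n_grid, tol)
    return _find_fixed_points_2d(flow, n_grid, tol)


# ---------------------------------------------------------------------------
# bifurcation scan

def bifurcation_scan(game: Union[PayoffMatrix, PayoffBimatrix],
                     params_base: DynParams,
                     lam_grid: Sequence[float],
                     n_grid: int = 256) -> BifurcationResult:
    """Track fixed-point branches over a lam grid; locate saddle-node values.

    Where the fixed-point count changes between consecutive grid points the
    critical lam is refined by bisection on the count to width LAMC_TOL and
    reported with its bracketing interval.  An empty lam_c list is a valid
    outcome (no bifurcation on the scanned range).
    """
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size < 16 or np.any(np.diff(lam_grid) <= 0):
        raise ValueError("lam_grid must be increasing with >= 16 points")
    two_pop = isinstance(game, PayoffBimatrix)

    def fps_at(lam: float) -> FixedPointSet:
        p = DynParams(Gamma=params_base.Gamma, lam=lam, u=params_base.u)
        if two_pop:
            return find_fixed_points(make_flow_2d(game, p), "2d", n_grid)
        return find_fixed_points(make_flow_1d(game, p), "1d", n_grid)

    branches = [fps_at(l) for l in lam_grid]
    counts = np.array([len(b) for b in branches])
    lam_c, brackets = [], []
    for i in np.nonzero(np.diff(counts) != 0)[0]:
        lo, hi = float(lam_grid[i]), float(lam_grid[i + 1])
        c_lo = counts[i]
        while hi - lo > LAMC_TOL:
            mid = 0.5 * (lo + hi)
            if len(fps_at(mid)) == c_lo:
                lo = mid
            else:
                hi = mid
        lam_c.append(0.5 * (lo + hi))
        brackets.append((lo, hi))
    return BifurcationResult(lam_grid=lam_grid, counts=counts, branches=branches,
                             lam_c=lam_c, lam_c_bracket=brackets)
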