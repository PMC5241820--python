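# Methods

## Model

### From learning to birth–death dynamics

We study two-strategy games under reinforcement learning with geometric
memory discounting. In the continuous-time limit the learning rule becomes
the Sato–Crutchfield dynamics: a replicator flow driven by the *modified
fitness*

    f_i = π_i − λ ln x_i,

where π_i is the average payoff of strategy i against the current (own or
opponent) mixed strategy, and λ ≥ 0 is the memory-loss strength. The
−λ ln x_i term acts entropically: it penalises ideas that are already
common and boosts rare ones, pushing the strategy toward the uniform mix.
The intensity of choice Γ ≥ 0 multiplies the whole flow and sets the
selection strength.

The finite-population representation replaces the mixed strategy by a
population of N idea-tokens. Transitions n → n±1 occur at rates
T± = N·x(1−x)·g(·,·) with the linear pairwise comparison probability
g(f₁, f₂) = [1 + Γ(f₁ − f₂)]/2. Two design facts follow from the linear
form and are exploited by the tests:

* **drift identity** — T⁺ − T⁻ = N x(1−x) Γ (f₁ − f₂), exactly the
  (entropic) replicator velocity, so the N → ∞ limit of the chain is the
  deterministic flow;
* **complementarity** — g(f₁,f₂) + g(f₂,f₁) = 1, so the per-state
  probability that a triplet-sampling event changes the composition is
  exactly x(1−x).

The factor N in the rates means one unit of time is one generation
(≈ N replacement events); all reported times use this unit.

States n = 0 and n = N are absorbing (x(1−x) kills both rates; the
entropic divergence is dominated, lim_{x→0} x ln x = 0). In the
two-population (asymmetric-game) chain on the (n, m) lattice the analogous
statement holds per coordinate, leaving exactly the four corners absorbing:
an idea population that has fixed stays fixed while the other keeps
evolving. This is the structural difference from replicator-mutator
dynamics, whose mutation flux u(1−2x) keeps the boundary alive
(flow = ±u there) and which therefore has no absorbing states.

### Rate positivity

g must be a probability at every interior state, which at fixed Γ bounds
the memory loss: the worst states are n = 1 and n = N−1 where
|λ ln(x/(1−x))| ≈ λ ln N is largest, giving an admissible
λ_max = O(1/ln N). `validate_rates` checks the whole lattice and reports
λ_max by bisection (60 halvings). g is deliberately **not clipped**:
clipping would silently change the model; out-of-range g raises instead.

### Triplet microsimulation

The linear comparison process has a per-encounter realisation: draw an
ordered triplet (primary, secondary, adversary) with replacement, let
primary and secondary each play the adversary once, and switch the
secondary to the primary's type with probability g applied to the two
*realised* payoffs. Averaging over the adversary reproduces the analytic
rates; the microsimulation verifies this as a Monte-Carlo identity. The
construction exists only for payoff-based fitness: ln x is a
population-level quantity with no single-encounter meaning, so the triplet
route is restricted to λ = 0 and λ > 0 simulation always goes through the
rate matrices. To accumulate per-state statistics the microsimulation
restarts from the initial state on absorption (the chain is Markov in n,
so interior transition probabilities are unaffected).

## Canonical game fixtures

All structural results exercised here (fixed-point counts, stability
patterns, scaling regimes) are properties of the game *class*, not of
specific payoff entries. The catalogue pins one documented representative
per class:

| name | payoffs | why this representative |
|---|---|---|
| coexistence | (1,3,2,1) | interior attractor at x* = 2/3 for λ = 0, visibly moving to 1/2 as λ grows (a symmetric variant would pin it at 1/2) |
| dominance | (3,1,2,0) | strategy 1 strictly dominant with constant payoff gap 1 |
| coordination | (2,0,0,1) | bistable, unstable interior point at 1/3; saddle-node at λ_c ≈ 0.321 |
| neutral | (1,1,1,1) | pure drift control |
| matching_pennies | A = [[1,−1],[−1,1]], B = −A | zero-sum (a_ij + b_ji = 0); cyclic flow around (1/2, 1/2) |
| asym_dominance | A = [[2,0],[1,−1]], B = [[1,−1],[−1,1]] | player A's action 1 strictly dominates; B coordinates with A, giving a unique stable corner (1,1) at λ = 0 |
| hyperbolic | A = B = [[1,−1],[−1,1]] | interior saddle flanked by two stable corners; the A↔B exchange symmetry makes both stable points merge with the saddle *simultaneously* at λ_c = 1 |

Γ = 0.1 is the default intensity of choice throughout: a standard
compromise between best-response (Γ ≈ 1) and weak selection (Γ ≪ 1). It
leaves a comfortable validity margin (λ well above 0.5 admissible at the
population sizes used here).

## Numerical policy

**Flows and integration.** Boundary evaluations of the entropic flows
return the limit value 0 instead of evaluating ln 0. Trajectories use
LSODA with rtol = atol = 1e−9 and dense output; states are clipped to the
simplex only within atol of the boundary.

**Fixed points (1D).** Sign-change bracketing on a uniform grid *augmented
with log-spaced points down to 1e−14 from either boundary*, followed by
Brent refinement to machine precision; boundaries tested explicitly. The
augmentation matters: interior fixed points sit at distance ≈ exp(−Δπ/λ)
from the boundary and a uniform grid misses them at small λ. This also
sets a hard representability limit: a root closer to 1.0 than float64
resolution (1.1e−16, i.e. λ < Δπ/36.7) cannot be distinguished from the
boundary by any double-precision root finder; tests therefore use λ ≥ 0.1
for "small memory loss" in the coordination game. Roots are deduplicated
at 1e−6 separation (interior ones may legitimately sit closer to the exact
boundary points and are kept). Classification by flow-sign probes on either
side (robust where the Jacobian diverges, e.g. boundaries at λ > 0, where
the derivative of −λx ln x is +∞ and the boundary is always repelling).

**Fixed points (2D).** Corners always tested; per-edge 1D searches with
the transverse coordinate frozen; interior roots from a seed grid
(uniform plus log-spaced near-corner diagonal seeds) refined with Powell's
hybrid method, accepting |flow| ≤ 1e−10 and deduplicating at 1e−6.
Interior points are classified by the eigenvalues of a central-difference
Jacobian: center iff |Re| < 1e−8 with nonzero imaginary parts (at the
Matching Pennies λ = 0 centre the diagonal derivatives vanish identically,
so finite differencing is exact there); boundary points by directional
probes as in 1D.

**Bifurcation scans.** Fixed-point count tracked across an increasing λ
grid (≥ 16 points); each count change refined by bisection on the count to
a λ-width of 1e−4 and reported with its bracketing interval. An empty
result is meaningful (coexistence has no bifurcation). Scan ranges are
chosen inside the representability limit above.

**Closed-form fixation sums.** The textbook birth-death expressions are
evaluated entirely in log space (running log-products of T⁻/T⁺ ratios,
`logaddexp` cumulative sums, signed log-difference for the step
increments): products of odds ratios across a strong-selection lattice
overflow double precision long before the final times do. Closed form and
backward-equation solve agree to ≈ 1e−13 relative on the fixtures; the
suite asserts 1e−8.

**Backward master equation.** Sparse assembly over transient states with
τ = 0 imposed at absorbing states; direct sparse LU (`spsolve`) at every
size used here (up to (241)² lattices, ≈ 58k unknowns, seconds). The 1D
fixation probability uses the same operator with boundary data 0/1.

**Monte Carlo.** One seeded generator per replicate; replicate seeds are
derived from the base seed with `numpy.random.SeedSequence(base).generate_state(reps)`,
making ensembles reproducible and parallelisable. Standard error is the
plain ensemble SD/√reps (replicates independent). Censoring (max_events,
default 1e9, or t_max) is flagged distinctly and censored replicates are
excluded from means and reported separately. The Gillespie cores are
numba-compiled; a pure-python fallback keeps the package importable
without numba.

**Diffusive exponent.** RMS distance from (1/2, 1/2) over log-spaced
sample times, fitted log-log over the window from the first crossing of
2/N to the first crossing of 0.25. The window must *reach* 0.25: if the
RMS distance saturates below it (metastable fluctuation around an interior
attractor, as for λ = 0.3) no diffusive window exists and the measurement
fails loudly rather than fitting a plateau.

**Scaling fits.** Least squares on each model's own linearisation
(log τ vs log N, log τ vs N, τ vs log N), compared side by side by R²; no
formal model-selection criterion is claimed. The deterministic
backward-equation τ is used for the activation (exponential) and
relaxation (logarithmic) regimes; the diffusive power law is measured by
Monte Carlo at N up to 420 (200 replicates), where the exponent fitted on
finite N grids is ≈ 0.9 and approaches 1 slowly from below (the τ = aN + b
offset biases a finite-size log-log slope downward).

**Multiple-comparison allowance.** Identity checks that perform ~10²
simultaneous per-state 3σ tests (triplet microsimulation) tolerate the
expected false-alarm count (≤ max(2, 2%)) instead of requiring a
seed-dependent perfect score.

## Study conditions and problem sizes

Symmetric-game fixation analyses use N = 200 from n₀ = N/2 (closed form /
backward equation are exact at any N; N = 1000–2000 variants are exposed
via the experiments' `full` flag). Two-population backward equations use
N = 30 (the (N+1)²-state linear system the heat maps are built from);
two-population Monte Carlo uses N = 100 (τ(λ) curves) and up to N = 500
(diffusive exponent, 200 replicates). The non-monotone τ(λ) scan for the
coordination game defaults to N = 400 and is reproduced at N = 1000 in the
closed-form route, where it is exact and cheap. Scaling grids:
{60, 100, 160, 260, 420} (diffusive), {30, 45, 60, 80} (activation,
exponential growth makes larger N pointless), {30, 60, 120, 240}
(relaxation).

## What the fixtures do and do not show

The synthetic game catalogue spans the qualitatively distinct 2×2 flow
topologies, which is what the fixation phenomenology depends on. Passing
tests establish the mechanism decomposition — relaxation, activation,
diffusion, and their scaling signatures — for these representatives; they
do not calibrate to any empirical payoff data, and quantitative values
(λ_c ≈ 0.321, fixation times) are fixture-specific. Known limitations:

* fixed points closer to the boundary than float64 resolution (λ below
  ≈ Δπ/36, depending on the payoff gap) are indistinguishable from the
  boundary;
* the triplet construction does not extend to λ > 0 (no per-encounter
  meaning of ln x);
* only S = 2 strategies; no Fermi-rule comparison process; no tau-leaping
  or diffusion-approximation simulation (exact SSA only);
* conditional fixation times and full first-passage distributions are out
  of scope (unconditional means only; the unconditional convention is also
  what the τ(λ) curves and heat maps report).
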