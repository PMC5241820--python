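import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ideapop as ip
from ideapop.dynamics import avg_payoff_1d
from ideapop.stochastic import (ChainParams, pairwise_comparison_g, rates_1d,
                                rates_2d, triplet_microsim, validate_rates)

fitness = st.floats(-10, 10, allow_nan=False, allow_infinity=False)


# ---------------------------------------------------------------------------
# pairwise comparison probability

def test_pairwise_comparison_basics():
    assert pairwise_comparison_g(1.3, 1.3, 0.5) == 0.5
    assert pairwise_comparison_g(3.0, -1.0, 0.0) == 0.5


@given(f1=fitness, f2=fitness, gamma=st.floats(0, 1))
def test_pairwise_comparison_complementarity(f1, f2, gamma):
    g12 = pairwise_comparison_g(f1, f2, gamma)
    g21 = pairwise_comparison_g(f2, f1, gamma)
    assert g12 + g21 == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# 1D rates

def test_neutral_rate_value():
    r = rates_1d(ip.make_symmetric_game("neutral"), ChainParams(N=4))
    assert r.tplus[2] == pytest.approx(0.5)
    assert r.tminus[2] == pytest.approx(0.5)


@pytest.mark.parametrize("name", ["coexistence", "dominance", "coordination"])
def test_boundary_states_are_absorbing(name):
    r = rates_1d(ip.make_symmetric_game(name), ChainParams(N=50, lam=0.2))
    assert r.tplus[0] == r.tminus[0] == 0.0
    assert r.tplus[50] == r.tminus[50] == 0.0
    assert r.absorbing_states() == [0, 50]


def test_rate_difference_is_modified_replicator_drift():
    """T+ - T- = N x(1-x) Gamma (f1 - f2): the linear g makes the chain's
    drift exactly the entropic replicator velocity."""
    g = ip.make_symmetric_game("coexistence")
    p = ChainParams(N=80, Gamma=0.1, lam=0.25)
    r = rates_1d(g, p)
    n = np.arange(1, 80)
    x = n / 80
    pi1, pi2 = avg_payoff_1d(g, x)
    f1 = pi1 - p.lam * np.log(x)
    f2 = pi2 - p.lam * np.log(1 - x)
    drift = 80 * x * (1 - x) * p.Gamma * (f1 - f2)
    assert np.allclose(r.tplus[n] - r.tminus[n], drift)


def test_rates_swap_symmetry():
    g = ip.make_symmetric_game("dominance")
    p = ChainParams(N=60, Gamma=0.1, lam=0.15)
    r = rates_1d(g, p)
    n = np.arange(1, 60)
    x = n / 60
    pi1, pi2 = avg_payoff_1d(g, x)
    f1 = pi1 - p.lam * np.log(x)
    f2 = pi2 - p.lam * np.log(1 - x)
    base = 60 * x * (1 - x)
    assert np.allclose(r.tminus[n], base * pairwise_comparison_g(f2, f1, p.Gamma))


# ---------------------------------------------------------------------------
# validation

def test_validation_passes_in_admissible_regime():
    g = ip.make_symmetric_game((3, -2, 1, 0))
    diag = validate_rates(g, ChainParams(N=200, Gamma=0.1, lam=0.0))
    assert diag.ok
    assert diag.lam_max > 0


def test_validation_fails_near_boundary_for_large_lam():
    g = ip.make_symmetric_game("dominance")
    r = rates_1d(g, ChainParams(N=200, Gamma=0.1, lam=10.0), check=False)
    diag = validate_rates(r)
    assert not diag.ok
    # worst states are near the boundary, where |ln x| is largest
    assert min(diag.bad_states) <= 5 or max(diag.bad_states) >= 195
    with pytest.raises(ValueError):
        rates_1d(g, ChainParams(N=200, Gamma=0.1, lam=10.0))


def test_admissible_lam_shrinks_with_population_size():
    g = ip.make_symmetric_game("dominance")
    lam_max = [validate_rates(g, ChainParams(N=N, Gamma=0.1)).lam_max
               for N in (100, 1000, 10000)]
    assert lam_max[0] > lam_max[1] > lam_max[2] > 0


# ---------------------------------------------------------------------------
# 2D rates

def test_two_population_corners_are_the_only_absorbing_states(matching_pennies):
    r = rates_2d(matching_pennies, ChainParams(N=30, Gamma=0.1, lam=0.3))
    assert sorted(r.absorbing_states()) == [(0, 0), (0, 30), (30, 0), (30, 30)]


def test_matching_pennies_centre_is_driftless(matching_pennies):
    N = 30
    r = rates_2d(matching_pennies, ChainParams(N=N, Gamma=0.1, lam=0.0))
    c = N // 2
    assert r.aplus[c, c] == pytest.approx(r.aminus[c, c])
    assert r.bplus[c, c] == pytest.approx(r.bminus[c, c])


def test_zero_bimatrix_reduces_to_neutral_chain():
    zero = ip.make_asymmetric_game(([[0, 0], [0, 0]], [[0, 0], [0, 0]]))
    N = 20
    r = rates_2d(zero, ChainParams(N=N, Gamma=0.1, lam=0.0))
    n = np.arange(1, N)
    expected = N * (n / N) * (1 - n / N) * 0.5
    assert np.allclose(r.aplus[n, 7], expected)
    assert np.allclose(r.bminus[7, n], expected)


# ---------------------------------------------------------------------------
# Gillespie

def test_absorbed_initial_state_terminates_immediately(symmetric_games):
    r = rates_1d(symmetric_games["dominance"], ChainParams(N=40))
    tr = ip.gillespie(r, 0, seed=1)
    assert tr.absorbed and tr.absorption_time == 0.0 and tr.n_events == 0


def test_fixed_seed_reproduces_trajectory(symmetric_games):
    r = rates_1d(symmetric_games["coexistence"], ChainParams(N=40, lam=0.1))
    a = ip.gillespie(r, 20, seed=99, record=True)
    b = ip.gillespie(r, 20, seed=99, record=True)
    assert np.array_equal(a.times, b.times)
    assert np.array_equal(a.states, b.states)


def test_recorded_trajectory_invariants(symmetric_games):
    r = rates_1d(symmetric_games["neutral"], ChainParams(N=30))
    tr = ip.gillespie(r, 15, seed=7, record=True)
    assert np.all(np.diff(tr.times) > 0)
    assert np.all(np.abs(np.diff(tr.states)) == 1)
    assert tr.absorbed
    assert tr.states[-1] in (0, 30)


def test_neutral_fixation_probability_is_martingale():
    """P(absorb at N) = n0/N for the drift-free chain."""
    r = rates_1d(ip.make_symmetric_game("neutral"), ChainParams(N=50))
    ens = ip.run_ensemble(r, 25, 2000, base_seed=13)
    upper = sum(1 for t in ens if t.absorption_state == (50,))
    p_hat = upper / 2000
    se = math.sqrt(0.25 / 2000)
    assert abs(p_hat - 0.5) < 3 * se


def test_all_replicates_absorb(symmetric_games):
    r = rates_1d(symmetric_games["coordination"], ChainParams(N=100, lam=0.2))
    ens = ip.run_ensemble(r, 50, 200, base_seed=5)
    assert all(t.absorbed for t in ens)


def test_gillespie_rejects_off_lattice_init(symmetric_games):
    r = rates_1d(symmetric_games["neutral"], ChainParams(N=30))
    with pytest.raises(ValueError):
        ip.gillespie(r, 31, seed=0)


def test_ensemble_mean_approaches_deterministic_flow(symmetric_games):
    """The chain's ensemble mean converges to the Sato-Crutchfield solution
    as N grows (weak noise limit)."""
    game = symmetric_games["coexistence"]
    p = ip.DynParams(Gamma=0.1, lam=0.2)
    flow = ip.make_flow_1d(game, p)
    det = ip.integrate_flow(flow, 0.9, 5.0, n_out=64)

    def sup_dist(N, reps=200):
        r = rates_1d(game, ChainParams(N=N, Gamma=0.1, lam=0.2))
        paths = np.empty((reps, det.times.size))
        for i, s in enumerate(ip.replicate_seeds(4321, reps)):
            tr = ip.gillespie(r, int(0.9 * N), seed=int(s), t_max=5.0,
                              record=True)
            idx = np.searchsorted(tr.times, det.times, side="right") - 1
            paths[i] = tr.states[idx] / N
        return np.max(np.abs(paths.mean(axis=0) - det.states))

    assert sup_dist(1000) < sup_dist(100)


# ---------------------------------------------------------------------------
# triplet microsimulation

def test_triplet_requires_zero_memory_loss(symmetric_games):
    with pytest.raises(ValueError):
        triplet_microsim(symmetric_games["neutral"],
                         ChainParams(N=20, lam=0.1), 10, 100)


def test_triplet_neutral_up_down_symmetry(symmetric_games):
    tc = triplet_microsim(symmetric_games["neutral"],
                          ChainParams(N=20, Gamma=0.1, seed=2), 10, 200_000)
    sel = tc.visits >= 1000
    up, down, v = tc.ups[sel], tc.downs[sel], tc.visits[sel]
    p = (up + down) / (2 * v)
    se = np.sqrt(p * (1 - p) * 2 / v).clip(1e-12)
    assert np.all(np.abs(up - down) / v <= 4 * se)


def test_triplet_change_frequency_is_x_one_minus_x(symmetric_games):
    """Triplets with equal primary/secondary types never change the
    composition, so P(change | state x) = x(1-x) exactly (the g's sum to 1)."""
    tc = triplet_microsim(symmetric_games["dominance"],
                          ChainParams(N=50, Gamma=0.1, seed=8), 25, 400_000)
    n = np.nonzero(tc.visits >= 2000)[0]
    x = n / 50
    p_change = (tc.ups[n] + tc.downs[n]) / tc.visits[n]
    expect = x * (1 - x)
    se = np.sqrt(expect * (1 - expect) / tc.visits[n])
    assert np.all(np.abs(p_change - expect) <= 4 * se)


def test_triplet_frequencies_match_birth_death_rates(symmetric_games):
    """Monte-Carlo check that averaging the pairwise comparison over the
    adversary reproduces the analytic transition rates."""
    game = symmetric_games["dominance"]
    p = ChainParams(N=100, Gamma=0.1, lam=0.0, seed=5)
    tc = triplet_microsim(game, p, init=50, n_events=10 ** 6)
    checked = violations = 0
    for n in range(1, 100):
        if tc.visits[n] < 500:
            continue
        x = n / 100
        pi1, pi2 = avg_payoff_1d(game, x)
        for emp_count, th in ((tc.ups[n], x * (1 - x) * pairwise_comparison_g(pi1, pi2, 0.1)),
                              (tc.downs[n], x * (1 - x) * pairwise_comparison_g(pi2, pi1, 0.1))):
            v = tc.visits[n]
            se = max(math.sqrt(th * (1 - th) / v), 1e-12)
            checked += 1
            if abs(emp_count / v - th) > 3 * se:
                violations += 1
    assert checked >= 50
    # per-state 3 sigma with ~100 simultaneous checks: allow the expected
    # handful of false alarms, not a systematic deviation
    assert violations <= max(2, int(0.02 * checked))
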