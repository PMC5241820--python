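import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import linregress

import ideapop as ip
from ideapop.dynamics import DynParams, make_flow_1d, make_flow_2d

payoff = st.floats(-5, 5, allow_nan=False, allow_infinity=False)
matrices = st.tuples(payoff, payoff, payoff, payoff).map(ip.make_symmetric_game)


# ---------------------------------------------------------------------------
# payoffs and fitness

@pytest.mark.parametrize("entries,x,expected", [
    ((1, 0, 0, 1), 0.5, (0.5, 0.5)),
    ((2, 0, 0, 1), 1.0, (2.0, 0.0)),
    ((1, 2, 2, 1), 0.25, (1.75, 1.25)),
])
def test_avg_payoff_1d(entries, x, expected):
    pi1, pi2 = ip.avg_payoff_1d(ip.make_symmetric_game(entries), x)
    assert pi1 == pytest.approx(expected[0])
    assert pi2 == pytest.approx(expected[1])


def test_avg_payoff_1d_matches_finite_population_formula():
    g = ip.make_symmetric_game((3, 1, 2, 0))
    N, n = 17, 5
    pi1, pi2 = ip.avg_payoff_1d(g, n / N)
    assert pi1 == pytest.approx((g.a11 * n + g.a12 * (N - n)) / N)
    assert pi2 == pytest.approx((g.a21 * n + g.a22 * (N - n)) / N)


def test_avg_payoff_2d(matching_pennies):
    vals = ip.avg_payoff_2d(matching_pennies, (0.5, 0.5))
    assert np.allclose(vals, vals[0])          # all four equal at the centre
    piA1, piA2, _, _ = ip.avg_payoff_2d(matching_pennies, (0.3, 1.0))
    assert piA1 == matching_pennies.A.a11      # pure opponent
    assert piA2 == matching_pennies.A.a21
    zero = ip.make_asymmetric_game(([[0, 0], [0, 0]], [[0, 0], [0, 0]]))
    assert ip.avg_payoff_2d(zero, (0.3, 0.7)) == (0, 0, 0, 0)


def test_avg_payoff_rejects_out_of_range():
    g = ip.make_symmetric_game("neutral")
    with pytest.raises(ValueError):
        ip.avg_payoff_1d(g, 1.2)


def test_modified_fitness():
    assert ip.modified_fitness(1.7, 0.3, 0.0) == 1.7
    assert ip.modified_fitness(0.0, 0.5, 1.0) == pytest.approx(math.log(2))
    # equal frequencies: entropic terms cancel in the difference
    f1 = ip.modified_fitness(2.0, 0.5, 0.7)
    f2 = ip.modified_fitness(1.0, 0.5, 0.7)
    assert f1 - f2 == pytest.approx(1.0)
    with pytest.raises(ValueError):
        ip.modified_fitness(1.0, 0.0, 0.5)


# ---------------------------------------------------------------------------
# flows

@given(m=matrices, lam=st.floats(0, 3), gamma=st.floats(0, 1))
def test_boundaries_are_fixed_points_of_entropic_flow(m, lam, gamma):
    p = DynParams(Gamma=gamma, lam=lam)
    assert ip.sc_flow_1d(m, 0.0, p) == 0.0
    assert ip.sc_flow_1d(m, 1.0, p) == 0.0


def test_entropic_force_pushes_toward_centre():
    neutral = ip.make_symmetric_game("neutral")
    p = DynParams(Gamma=0.1, lam=0.5)
    assert ip.sc_flow_1d(neutral, 0.25, p) > 0
    assert ip.sc_flow_1d(neutral, 0.75, p) < 0


@given(m=matrices, x=st.floats(0, 1), gamma=st.floats(0, 2))
def test_zero_memory_loss_recovers_replicator_flow(m, x, gamma):
    p = DynParams(Gamma=gamma, lam=0.0)
    from ideapop.dynamics import replicator_flow_1d
    assert ip.sc_flow_1d(m, x, p) == pytest.approx(
        gamma * replicator_flow_1d(m, x), abs=1e-12)


def test_two_population_flow(matching_pennies):
    p0 = DynParams(Gamma=0.1, lam=0.0)
    assert ip.sc_flow_2d(matching_pennies, (0.5, 0.5), p0) == (0.0, 0.0)
    assert ip.sc_flow_2d(matching_pennies, (0.0, 0.0), DynParams(0.1, 0.7)) == (0.0, 0.0)


def test_replicator_mutator_has_no_absorbing_boundary():
    neutral = ip.make_symmetric_game("neutral")
    p = DynParams(Gamma=0.1, u=0.1)
    assert ip.replicator_mutator_flow(neutral, 0.0, p) == pytest.approx(0.1)
    assert ip.replicator_mutator_flow(neutral, 1.0, p) == pytest.approx(-0.1)
    p0 = DynParams(Gamma=0.1, u=0.0)
    xs = np.linspace(0, 1, 33)
    g = ip.make_symmetric_game("dominance")
    assert np.allclose(ip.replicator_mutator_flow(g, xs, p0),
                       ip.sc_flow_1d(g, xs, p0))


# ---------------------------------------------------------------------------
# integration

def test_integrate_constant_for_zero_flow():
    traj = ip.integrate_flow(lambda x: 0.0, 0.3, 10.0)
    assert np.allclose(traj.states, 0.3)


def test_coordination_converges_above_unstable_point(symmetric_games):
    flow = make_flow_1d(symmetric_games["coordination"], DynParams(0.1, 0.0))
    traj = ip.integrate_flow(flow, 0.5, 2000.0)
    assert traj.states[-1] == pytest.approx(1.0, abs=1e-6)


def test_dominance_approach_is_exponential(symmetric_games):
    flow = make_flow_1d(symmetric_games["dominance"], DynParams(0.1, 0.0))
    traj = ip.integrate_flow(flow, 0.5, 120.0, n_out=400)
    dist = 1.0 - traj.states
    tail = (traj.times > 20) & (dist > 1e-12)
    res = linregress(traj.times[tail], np.log(dist[tail]))
    assert res.rvalue ** 2 > 0.99
    assert res.slope < 0


def test_matching_pennies_orbits_close(matching_pennies):
    """lam = 0 zero-sum flow conserves a quantity: orbits are closed."""
    flow = make_flow_2d(matching_pennies, DynParams(0.1, 0.0))
    traj = ip.integrate_flow(flow, (0.7, 0.5), 200.0, n_out=8192)
    d = np.hypot(traj.states[:, 0] - 0.7, traj.states[:, 1] - 0.5)
    assert d[traj.times > 10].min() < 1e-4


# ---------------------------------------------------------------------------
# fixed points

def test_coordination_fixed_point_counts(symmetric_games):
    game = symmetric_games["coordination"]
    for lam, expected in ((0.0, 3), (0.1, 5), (0.5, 3)):
        fps = ip.find_fixed_points(make_flow_1d(game, DynParams(0.1, lam)), "1d")
        assert len(fps) == expected, lam


def test_coordination_reversed_stability_beyond_bifurcation(symmetric_games):
    fps = ip.find_fixed_points(
        make_flow_1d(symmetric_games["coordination"], DynParams(0.1, 0.5)), "1d")
    by_loc = {p.location[0]: p.stability for p in fps}
    assert by_loc[0.0] == "unstable"
    assert by_loc[1.0] == "unstable"
    interior = [p for p in fps.interior()]
    assert len(interior) == 1 and interior[0].stability == "stable"


@pytest.mark.parametrize("name", ["coexistence", "dominance", "coordination"])
def test_attractors_are_interior_for_positive_memory_loss(symmetric_games, name):
    # lam >= 0.1: interior points can sit at distance ~exp(-c/lam) from the
    # boundary and must stay above float64 resolution to be located at all
    game = symmetric_games[name]
    for lam in (0.1, 0.2, 0.5, 1.0):
        fps = ip.find_fixed_points(make_flow_1d(game, DynParams(0.1, lam)), "1d")
        for p in fps:
            if p.stability == "stable":
                assert 0 < p.location[0] < 1


@pytest.mark.parametrize("name", ["coexistence", "dominance", "coordination"])
def test_large_memory_loss_pins_attractor_at_half(symmetric_games, name):
    fps = ip.find_fixed_points(
        make_flow_1d(symmetric_games[name], DynParams(0.1, 1000.0)), "1d")
    stable = [p for p in fps.interior() if p.stability == "stable"]
    assert len(stable) == 1
    assert abs(stable[0].location[0] - 0.5) < 1e-3


def test_matching_pennies_centre_becomes_attractor(matching_pennies):
    fps0 = ip.find_fixed_points(
        make_flow_2d(matching_pennies, DynParams(0.1, 0.0)), "2d")
    centre0 = [p for p in fps0.interior()]
    assert len(centre0) == 1
    assert centre0[0].location == pytest.approx((0.5, 0.5), abs=1e-8)
    assert centre0[0].stability == "center"

    fps3 = ip.find_fixed_points(
        make_flow_2d(matching_pennies, DynParams(0.1, 0.3)), "2d")
    centre3 = [p for p in fps3.interior()
               if np.allclose(p.location, (0.5, 0.5), atol=1e-6)]
    assert centre3[0].stability == "stable"


def test_find_fixed_points_rejects_coarse_grid():
    with pytest.raises(ValueError):
        ip.find_fixed_points(lambda x: x * (1 - x), "1d", n_grid=10)


# ---------------------------------------------------------------------------
# bifurcation scans

def test_coexistence_has_no_bifurcation(symmetric_games):
    res = ip.bifurcation_scan(symmetric_games["coexistence"], DynParams(0.1),
                              np.linspace(0.0, 0.6, 20))
    assert res.lam_c == []
    # single interior stable branch moving toward 1/2
    locs = []
    for fps in res.branches:
        stable = [p.location[0] for p in fps.interior() if p.stability == "stable"]
        assert len(stable) == 1
        locs.append(stable[0])
    assert locs[0] == pytest.approx(2 / 3, abs=1e-8)
    assert np.all(np.diff(np.abs(np.array(locs) - 0.5)) < 0)


def test_coordination_saddle_node(symmetric_games):
    res = ip.bifurcation_scan(symmetric_games["coordination"], DynParams(0.1),
                              np.linspace(0.1, 0.6, 21))
    assert len(res.lam_c) == 1
    assert set(res.counts.tolist()) == {3, 5}
    lam_c = res.lam_c[0]
    assert 0.25 < lam_c < 0.4
    lo, hi = res.lam_c_bracket[0]
    assert hi - lo <= 1.0001e-4


def test_hyperbolic_stable_pair_merges_with_saddle(hyperbolic):
    res = ip.bifurcation_scan(hyperbolic, DynParams(0.1),
                              np.linspace(0.8, 1.2, 17), n_grid=144)
    assert len(res.lam_c) >= 1
    before = res.branches[0]
    after = res.branches[-1]
    assert sum(1 for p in before.interior() if p.stability == "stable") == 2
    assert sum(1 for p in before.interior() if p.stability == "saddle") == 1
    inner_after = after.interior()
    assert sum(1 for p in inner_after if p.stability == "stable") == 1
    assert all(p.stability != "saddle" for p in inner_after
               if np.allclose(p.location, (0.5, 0.5), atol=1e-6))
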