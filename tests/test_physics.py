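import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from crowdcrush import (AgentSpec, AgentState, ConvergenceError,
                        NonFiniteStateError, PhysicsParams, ScenarioSpec,
                        compress_pressure, compress_to, contact_force_pair,
                        relax, repulsive_force, step, wall_forces)
from crowdcrush.physics import (WorldState, forces, initial_state,
                                piston_reaction_force)
from conftest import random_world


def _agent(x, y, theta=0.0, vel=(0.0, 0.0), omega=0.0, id=0):
    return AgentState(id=id, position=np.array([x, y], dtype=float),
                      orientation=theta, velocity=np.array(vel, dtype=float),
                      angular_velocity=omega)


# ---------------------------------------------------------------------------
# repulsion


def test_repulsion_hand_value(params):
    """(p_i - p_j) * C * w with w = 1 - d/D: 0.3 m apart at C=200, D=0.6."""
    F = repulsive_force(_agent(0, 0), [_agent(0.3, 0.0, id=1)], params)
    assert F == pytest.approx([-30.0, 0.0], abs=1e-12)


def test_repulsion_vanishes_at_and_beyond_threshold(params):
    for d in (0.6, 0.75):
        F = repulsive_force(_agent(0, 0), [_agent(d, 0.0, id=1)], params)
        assert F == pytest.approx([0.0, 0.0], abs=0.0)


def test_repulsion_symmetric_cancellation(params):
    """Middle of three equally spaced collinear agents feels zero net force."""
    left, right = _agent(-0.25, 0.0, id=1), _agent(0.25, 0.0, id=2)
    F = repulsive_force(_agent(0, 0), [left, right], params)
    assert F == pytest.approx([0.0, 0.0], abs=1e-12)


# ---------------------------------------------------------------------------
# contacts


def test_contact_disjoint_footprints_zero(agent, params):
    a = _agent(1.0, 1.0)
    b = _agent(1.0 + 2 * agent.semi_major + 0.01, 1.0, id=1)
    Fa, ta, Fb, tb = contact_force_pair(a, b, agent, params)
    assert np.all(Fa == 0.0) and np.all(Fb == 0.0) and ta == 0.0 and tb == 0.0


def test_contact_penalty_hand_value(agent, params):
    """Exactly one circle pair overlapping by 1 cm at k = 1e5 N/m -> 1000 N.

    Both agents lie along the line of centers 0.49 m apart, so a's leading
    circle (at +0.125 m) and b's trailing circle (at -0.125 m) are 0.24 m
    apart — a 0.01 m overlap of the 0.125 m circles — while every other
    circle pair stays disjoint.
    """
    a = _agent(0.0, 0.0, theta=0.0)
    b = _agent(0.49, 0.0, theta=0.0, id=1)
    Fa, ta, Fb, tb = contact_force_pair(a, b, agent, params)
    assert np.hypot(*Fa) == pytest.approx(1000.0, rel=1e-9)
    assert Fa[0] == pytest.approx(-1000.0, rel=1e-9)  # pushes a away from b
    assert ta == pytest.approx(0.0, abs=1e-12)  # force passes along the axis
    np.testing.assert_array_equal(Fb, -Fa)


@given(seed=st.integers(0, 10_000))
def test_contact_newton_third_law_exact(seed, agent, params):
    """Pair forces cancel to the bit for arbitrary poses and velocities."""
    rng = np.random.default_rng(seed)
    a = _agent(*rng.uniform(0, 0.4, 2), theta=rng.uniform(0, 2 * np.pi),
               vel=rng.normal(0, 1, 2), omega=rng.normal())
    b = _agent(*rng.uniform(0, 0.4, 2), theta=rng.uniform(0, 2 * np.pi),
               vel=rng.normal(0, 1, 2), omega=rng.normal(), id=1)
    Fa, _, Fb, _ = contact_force_pair(a, b, agent, params)
    np.testing.assert_array_equal(Fb, -Fa)


@given(seed=st.integers(0, 10_000))
def test_kernel_pair_cancellation_exact(seed, agent, params):
    """The integrator's own pair forces obey Newton's third law bitwise."""
    w = random_world(2, seed, box=(6.0, 6.0), crammed=True)
    w.positions += np.array([2.0, 2.0])  # keep clear of every wall
    f, tq, load = forces(w, agent, params)
    np.testing.assert_array_equal(f[0], -f[1])
    assert load == 0.0


# ---------------------------------------------------------------------------
# walls


def test_wall_forces_interior_agent_zero(agent, params):
    spec = ScenarioSpec(n_agents=1, length_L=4.0, width_W=4.0, agents_per_row=1)
    w = WorldState(scenario=spec, ids=[0], positions=[[2.0, 2.0]],
                   orientations=[0.3], velocities=[[0, 0]],
                   angular_velocities=[0.0])
    f, t = wall_forces(w, agent, params)
    assert np.all(f == 0.0) and np.all(t == 0.0)


def test_wall_penalty_hand_value(agent, params):
    """Each 0.125 m circle whose center sits 0.120 m from a wall: 500 N."""
    spec = ScenarioSpec(n_agents=1, length_L=4.0, width_W=4.0, agents_per_row=1)
    # side-on to the left wall: all three circles at x = 0.120
    w = WorldState(scenario=spec, ids=[0], positions=[[0.120, 2.0]],
                   orientations=[math.pi / 2], velocities=[[0, 0]],
                   angular_velocities=[0.0])
    f, t = wall_forces(w, agent, params)
    assert f[0, 0] == pytest.approx(3 * 500.0, rel=1e-9)
    assert f[0, 1] == pytest.approx(0.0, abs=1e-9)
    assert t[0] == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# kernel consistency


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_kernel_matches_reference_force_laws(seed, agent, params):
    """Kernel forces = repulsion + pair contacts + wall penalties (oracles)."""
    w = random_world(10, seed, box=(3.0, 1.5))
    f, tq, _ = forces(w, agent, params)
    agents = w.agents
    wf, wt = wall_forces(w, agent, params)
    for i, ai in enumerate(agents):
        expect_f = repulsive_force(ai, [a for a in agents if a.id != ai.id],
                                   params) + wf[i]
        expect_t = wt[i]
        for aj in agents:
            if aj.id == ai.id:
                continue
            Fa, ta, _, _ = contact_force_pair(ai, aj, agent, params)
            expect_f = expect_f + Fa
            expect_t += ta
        np.testing.assert_allclose(f[i], expect_f, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(tq[i], expect_t, rtol=1e-9, atol=1e-9)


@pytest.mark.parametrize("seed", [3, 11])
def test_spatial_hash_identical_to_all_pairs(seed, agent, params):
    """Cell-list neighbour search reproduces the all-pairs loop bit-for-bit."""
    p_all = dataclasses.replace(params, use_spatial_hash=False)
    w = random_world(25, seed, box=(5.0, 3.0), crammed=(seed % 2 == 0))
    f1, t1, l1 = forces(w, agent, params)
    f2, t2, l2 = forces(w, agent, p_all)
    np.testing.assert_array_equal(f1, f2)
    np.testing.assert_array_equal(t1, t2)
    assert l1 == l2
    s1 = step(w, agent, params, 200)
    s2 = step(w, agent, p_all, 200)
    np.testing.assert_array_equal(s1.positions, s2.positions)
    np.testing.assert_array_equal(s1.orientations, s2.orientations)


# ---------------------------------------------------------------------------
# integration


def test_isolated_agent_at_rest_stays_put(agent, params):
    spec = ScenarioSpec(n_agents=1, length_L=4.0, width_W=4.0, agents_per_row=1)
    w = WorldState(scenario=spec, ids=[0], positions=[[2.0, 2.0]],
                   orientations=[1.0], velocities=[[0, 0]],
                   angular_velocities=[0.0])
    after = step(w, agent, params, 50)
    np.testing.assert_array_equal(after.positions, w.positions)
    np.testing.assert_array_equal(after.orientations, w.orientations)


def test_free_agent_speed_decays_geometrically(agent, params):
    """With zero force, speed shrinks by the dissipation factor each step."""
    spec = ScenarioSpec(n_agents=1, length_L=40.0, width_W=40.0,
                        agents_per_row=1)
    v0 = 0.01
    w = WorldState(scenario=spec, ids=[0], positions=[[20.0, 20.0]],
                   orientations=[0.0], velocities=[[v0, 0]],
                   angular_velocities=[0.0])
    n = 10
    after = step(w, agent, params, n)
    expected = v0 * (1.0 - params.global_dissipation) ** n
    assert after.velocities[0, 0] == pytest.approx(expected, rel=1e-12)
    # kinetic energy is strictly non-increasing without contacts
    ke = [w.kinetic_energy(agent)]
    cur = w
    for _ in range(5):
        cur = step(cur, agent, params, 1)
        ke.append(cur.kinetic_energy(agent))
    assert all(b < a for a, b in zip(ke, ke[1:]))


def test_overlapping_agents_separate(agent, params):
    spec = ScenarioSpec(n_agents=2, length_L=6.0, width_W=6.0, agents_per_row=2)
    w = WorldState(scenario=spec, ids=[0, 1],
                   positions=[[3.0, 3.0], [3.45, 3.0]],
                   orientations=[0.0, 0.0], velocities=np.zeros((2, 2)),
                   angular_velocities=[0.0, 0.0])
    dist = [0.45]
    cur = w
    for _ in range(5):
        cur = step(cur, agent, params, 10)
        dist.append(float(np.linalg.norm(cur.positions[1] - cur.positions[0])))
    assert all(b > a for a, b in zip(dist, dist[1:]))


def test_relaxation_dissipates_energy(agent, params, tiny_spec):
    """A jostled crowd settles: KE at convergence is below the tolerance."""
    w = initial_state(tiny_spec, agent)
    w.velocities += 0.2
    settled = relax(w, agent, params)
    assert settled.kinetic_energy(agent) < params.relax_tolerance


def test_compress_to_noop_leaves_converged_state(agent, params, tiny_spec):
    settled = relax(initial_state(tiny_spec, agent), agent, params)
    again = compress_to(settled, settled.piston_displacement, agent, params)
    moved = np.abs(again.positions - settled.positions).max()
    assert moved < 1e-3


def test_compression_confines_agents(agent, params, tiny_spec):
    settled = relax(initial_state(tiny_spec, agent), agent, params)
    out = compress_to(settled, 0.3, agent, params)
    assert out.piston_displacement == pytest.approx(0.3)
    slack = agent.semi_minor
    assert out.positions[:, 1].min() > 0.3 - slack
    assert out.positions[:, 1].max() < tiny_spec.width_W + slack
    assert out.positions[:, 0].min() > -slack
    assert out.positions[:, 0].max() < tiny_spec.length_L + slack
    # piston never retreats
    with pytest.raises(ValueError, match="retreat"):
        compress_to(out, 0.1, agent, params)


def test_trajectories_reproducible_bit_exactly(agent, params, tiny_spec):
    a = compress_to(relax(initial_state(tiny_spec, agent), agent, params),
                    0.2, agent, params)
    b = compress_to(relax(initial_state(tiny_spec, agent), agent, params),
                    0.2, agent, params)
    np.testing.assert_array_equal(a.positions, b.positions)
    np.testing.assert_array_equal(a.orientations, b.orientations)
    np.testing.assert_array_equal(a.velocities, b.velocities)


def test_pressure_mode_balances_piston_load(agent, params):
    """One rigid row wall-to-wall: piston settles where the total penalty
    force matches the 4450 N/m line load on the 10.27 m wall."""
    spec = ScenarioSpec(n_agents=20, length_L=10.27, width_W=1.0,
                        agents_per_row=20, rng_seed=0)
    w = initial_state(spec, agent)
    w.orientations[:] = 0.0  # shoulders parallel to the piston
    settled = compress_pressure(relax(w, agent, params), agent, params)
    load = spec.piston_pressure * spec.length_L
    assert piston_reaction_force(settled, agent, params) == pytest.approx(
        load, rel=0.01)
    assert 0.0 < settled.piston_displacement < spec.width_W


def test_convergence_failure_reports_residual(agent, tiny_spec):
    p = PhysicsParams(max_relax_steps=3, relax_tolerance=1e-12)
    w = initial_state(tiny_spec, agent)
    w.velocities += 1.0
    with pytest.raises(ConvergenceError) as err:
        relax(w, agent, p)
    assert err.value.residual_energy > 0.0


def test_non_finite_state_names_agent(agent, params, tiny_spec):
    w = initial_state(tiny_spec, agent)
    w.positions[2, 0] = np.nan
    with pytest.raises(NonFiniteStateError) as err:
        step(w, agent, params, 1)
    assert err.value.agent_id == 2


def test_params_validation():
    with pytest.raises(ValueError):
        PhysicsParams(timestep_dt=0.0)
    with pytest.raises(ValueError):
        PhysicsParams(global_dissipation=1.5)
    with pytest.raises(ValueError, match="neighbor_threshold_D"):
        PhysicsParams(neighbor_threshold_D=0.2).validate_against(AgentSpec())
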