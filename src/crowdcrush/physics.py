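"""Damped quasi-static rigid-body dynamics for compressed crowds.

Forces acting on each elliptical agent:

* a pairwise repulsion ``F_r = sum_j (p_i - p_j) * C * w_ij`` with
  ``w_ij = max(0, 1 - d_ij / D)`` over neighbours closer than ``D`` — the
  personal-space force that keeps a standing crowd spread out;
* penalty contacts between elliptical footprints, each footprint
  approximated by three circles of radius ``semi_minor`` spaced along the
  major axis; overlapping circle pairs push apart with normal force
  ``k * delta + c * (closing speed)``.  The finite stiffness ``k`` is the
  model of torso compressibility: under piston load agents interpenetrate,
  which stands in for chest compression;
* penalty forces from the three fixed walls and the moving piston plane
  (stiffness ``kw``);
* velocity damping — the per-body coefficients plus a global dissipation
  factor ``gamma`` applied every step, which keeps the compression
  quasi-static (the crowd is always near mechanical equilibrium).

Integration is semi-implicit Euler.  The piston either travels at a fixed
speed to a target displacement (displacement-controlled, the default) or is
a damped 1-DOF body loaded with ``piston_pressure * length_L`` newtons
(pressure-controlled) and settles at force balance.

The inner loop is compiled with numba.  The neighbour search uses a spatial
hash (uniform cell grid) feeding a Verlet pair list with a 0.1 m skin,
rebuilt whenever any agent has moved more than half the skin; pairs are
stored in ascending (i, j) order and re-tested against the true cutoff
every step, so the accelerated search is guaranteed (and tested) to produce
bit-identical trajectories to the all-pairs loop.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .scenario import TWO_PI, AgentSpec, AgentState, ScenarioSpec

logger = logging.getLogger(__name__)

# status codes returned by the simulation kernel
_OK = 0
_NO_CONVERGENCE = 1
_NON_FINITE = 2
_PAIR_OVERFLOW = 3

# consecutive sub-tolerance steps required before declaring equilibrium;
# guards against the trivially zero kinetic energy of a freshly packed crowd
SETTLE_WINDOW = 25


class PhysicsError(RuntimeError):
    pass


class ConvergenceError(PhysicsError):
    """Relaxation failed to reach the kinetic-energy tolerance in budget."""

    def __init__(self, msg: str, residual_energy: float):
        super().__init__(msg)
        self.residual_energy = residual_energy


class NonFiniteStateError(PhysicsError):
    """Integration produced a non-finite pose; names the offending agent."""

    def __init__(self, agent_id: int):
        super().__init__(f"non-finite state for agent {agent_id} after update")
        self.agent_id = agent_id


@dataclass(frozen=True)
class PhysicsParams:
    """Force constants, damping, and integrator settings (SI units).

    Defaults are sized for 50 kg agents under a 4450 N/m piston line load:
    ``contact_stiffness_k`` lets one agent carrying its share of that load
    penetrate a few centimetres, and ``global_dissipation`` overdamps the
    dynamics so every recorded state is effectively static.
    """

    repulsion_constant_C: float = 200.0      # N, Eq-(1)-style constant force
    neighbor_threshold_D: float = 0.6        # m, repulsion cutoff
    contact_stiffness_k: float = 1.0e5       # N/m, agent-agent penalty
    wall_stiffness_kw: float = 1.0e5         # N/m, agent-wall penalty
    contact_damping: float = 1.0e3           # N s/m, normal dashpot
    timestep_dt: float = 1.0e-3              # s
    relax_tolerance: float = 1.0e-3          # J, total KE at equilibrium
    piston_speed: float = 0.1                # m/s, displacement mode
    global_dissipation: float = 0.05         # per-step velocity factor (1-gamma)
    max_relax_steps: int = 400_000           # budget per relaxation phase
    packing_settle_steps: int = 10_000       # pre-compression settle horizon
    piston_mass: float = 500.0               # kg, pressure mode 1-DOF body
    use_spatial_hash: bool = True

    def __post_init__(self) -> None:
        positive = [
            self.repulsion_constant_C, self.neighbor_threshold_D,
            self.contact_stiffness_k, self.wall_stiffness_kw,
            self.timestep_dt, self.relax_tolerance, self.piston_speed,
            self.piston_mass,
        ]
        if any(v <= 0.0 for v in positive):
            raise ValueError("all PhysicsParams except contact_damping must be > 0")
        if self.contact_damping < 0.0:
            raise ValueError("contact_damping must be >= 0")
        if not (0.0 < self.global_dissipation < 1.0):
            raise ValueError("global_dissipation must lie in (0, 1)")
        if self.max_relax_steps < 1:
            raise ValueError("max_relax_steps must be >= 1")

    def validate_against(self, agent: AgentSpec) -> None:
        """Check couplings between force constants and body geometry."""
        if self.neighbor_threshold_D <= 2.0 * agent.semi_minor:
            raise ValueError(
                f"neighbor_threshold_D={self.neighbor_threshold_D} must exceed "
                f"2*semi_minor={2 * agent.semi_minor}; repulsion would never "
                "act between near-touching agents"
            )


@dataclass
class WorldState:
    """Array-of-structs snapshot of the whole simulation.

    ``piston_displacement`` is how far the piston plane (initially at y=0)
    has advanced into the enclosure; agents occupy
    ``[piston_displacement, width_W]`` in y.
    """

    scenario: ScenarioSpec
    ids: np.ndarray
    positions: np.ndarray       # (N, 2)
    orientations: np.ndarray    # (N,)
    velocities: np.ndarray      # (N, 2)
    angular_velocities: np.ndarray  # (N,)
    piston_displacement: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        n = self.scenario.n_agents
        self.ids = np.asarray(self.ids, dtype=np.int64).reshape(n)
        self.positions = np.ascontiguousarray(self.positions, dtype=float).reshape(n, 2)
        self.orientations = np.asarray(self.orientations, dtype=float).reshape(n)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float).reshape(n, 2)
        self.angular_velocities = np.asarray(
            self.angular_velocities, dtype=float
        ).reshape(n)
        if len(set(self.ids.tolist())) != n:
            raise ValueError("agent ids must be unique")
        if not (0.0 <= self.piston_displacement < self.scenario.width_W):
            raise ValueError(
                f"piston displacement {self.piston_displacement} outside "
                f"[0, {self.scenario.width_W})"
            )

    @classmethod
    def from_agents(cls, scenario: ScenarioSpec, agents: Sequence[AgentState],
                    piston_displacement: float = 0.0) -> "WorldState":
        return cls(
            scenario=scenario,
            ids=np.array([a.id for a in agents]),
            positions=np.array([a.position for a in agents]),
            orientations=np.array([a.orientation for a in agents]),
            velocities=np.array([a.velocity for a in agents]),
            angular_velocities=np.array([a.angular_velocity for a in agents]),
            piston_displacement=piston_displacement,
        )

    @property
    def agents(self) -> list[AgentState]:
        return [
            AgentState(
                id=int(self.ids[i]),
                position=self.positions[i],
                orientation=float(self.orientations[i]),
                velocity=self.velocities[i],
                angular_velocity=float(self.angular_velocities[i]),
            )
            for i in range(len(self.ids))
        ]

    @property
    def free_width(self) -> float:
        return self.scenario.width_W - self.piston_displacement

    def copy(self) -> "WorldState":
        return WorldState(
            scenario=self.scenario,
            ids=self.ids.copy(),
            positions=self.positions.copy(),
            orientations=self.orientations.copy(),
            velocities=self.velocities.copy(),
            angular_velocities=self.angular_velocities.copy(),
            piston_displacement=self.piston_displacement,
            time=self.time,
        )

    def kinetic_energy(self, agent: AgentSpec) -> float:
        ke = 0.5 * agent.mass * float(np.sum(self.velocities**2))
        ke += 0.5 * agent.moment_of_inertia * float(
            np.sum(self.angular_velocities**2)
        )
        return ke


def initial_state(scenario: ScenarioSpec, agent: AgentSpec | None = None) -> WorldState:
    """Hex-packed crowd as a WorldState (before any relaxation)."""
    from .scenario import hex_pack_arrays

    agent = agent or AgentSpec()
    positions, orientations = hex_pack_arrays(scenario, agent)
    n = scenario.n_agents
    return WorldState(
        scenario=scenario,
        ids=np.arange(n),
        positions=positions,
        orientations=orientations,
        velocities=np.zeros((n, 2)),
        angular_velocities=np.zeros(n),
    )


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True, inline="always")
def _degenerate_normal(i, j, seed):
    """Deterministic pseudo-random unit normal for coincident circle centers."""
    lo = min(i, j)
    hi = max(i, j)
    u = (seed ^ (lo * 73856093) ^ (hi * 19349663)) & 0x7FFFFFFF
    ang = u * (TWO_PI / 2147483648.0)
    nx = math.cos(ang)
    ny = math.sin(ang)
    if i > j:
        nx = -nx
        ny = -ny
    return nx, ny


@njit(cache=True)
def _pair_forces(i, j, pos, cth, sth, vel, omega, fx, fy, tq,
                 a, b, C, D, k, cdamp, seed, degen_count):
    """Accumulate repulsion + contact forces for the unordered pair (i, j).

    Force on j is the exact IEEE negation of the force on i by construction
    (Newton's third law holds to the bit).
    """
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    d2 = dx * dx + dy * dy
    cutoff = max(D, 2.0 * a)
    if d2 >= cutoff * cutoff:
        return
    d = math.sqrt(d2)

    if d < D:
        w = 1.0 - d / D
        cf = C * w
        fx[i] += dx * cf
        fy[i] += dy * cf
        fx[j] -= dx * cf
        fy[j] -= dy * cf

    if d < 2.0 * a:
        off = a - b
        two_b = 2.0 * b
        four_b2 = two_b * two_b
        for ki in range(-1, 2):
            cix = pos[i, 0] + ki * off * cth[i]
            ciy = pos[i, 1] + ki * off * sth[i]
            for kj in range(-1, 2):
                cjx = pos[j, 0] + kj * off * cth[j]
                cjy = pos[j, 1] + kj * off * sth[j]
                ddx = cix - cjx
                ddy = ciy - cjy
                dd2 = ddx * ddx + ddy * ddy
                if dd2 >= four_b2:
                    continue
                dist = math.sqrt(dd2)
                delta = two_b - dist
                if delta <= 0.0:
                    continue
                if dist < 1.0e-12:
                    nx, ny = _degenerate_normal(i, j, seed)
                    degen_count[0] += 1
                else:
                    nx = ddx / dist
                    ny = ddy / dist
                # mid-overlap application point
                pmx = 0.5 * (cix + cjx)
                pmy = 0.5 * (ciy + cjy)
                rix = pmx - pos[i, 0]
                riy = pmy - pos[i, 1]
                rjx = pmx - pos[j, 0]
                rjy = pmy - pos[j, 1]
                # contact-point velocities incl. rotation
                vix = vel[i, 0] - omega[i] * riy
                viy = vel[i, 1] + omega[i] * rix
                vjx = vel[j, 0] - omega[j] * rjy
                vjy = vel[j, 1] + omega[j] * rjx
                closing = -((vix - vjx) * nx + (viy - vjy) * ny)
                fm = k * delta + cdamp * closing
                if fm < 0.0:
                    fm = 0.0
                fxc = fm * nx
                fyc = fm * ny
                fx[i] += fxc
                fy[i] += fyc
                fx[j] -= fxc
                fy[j] -= fyc
                tq[i] += rix * fyc - riy * fxc
                tq[j] += -(rjx * fyc - rjy * fxc)


@njit(cache=True)
def _wall_forces(i, pos, cth, sth, fx, fy, tq, L, W, piston_y, a, b, kw):
    """Penalty forces from the three fixed walls and the piston plane.

    Returns this agent's normal-force contribution pressing on the piston.
    """
    off = a - b
    reaction = 0.0
    for kk in range(-1, 2):
        cx = pos[i, 0] + kk * off * cth[i]
        cy = pos[i, 1] + kk * off * sth[i]
        rx = cx - pos[i, 0]
        ry = cy - pos[i, 1]
        # left wall x = 0 (outward normal +x)
        delta = b - cx
        if delta > 0.0:
            f = kw * delta
            fx[i] += f
            tq[i] += -ry * f
        # right wall x = L
        delta = b - (L - cx)
        if delta > 0.0:
            f = kw * delta
            fx[i] -= f
            tq[i] += ry * f
        # far fixed wall y = W
        delta = b - (W - cy)
        if delta > 0.0:
            f = kw * delta
            fy[i] -= f
            tq[i] += rx * f
        # piston plane y = piston_y (pushes agents in +y)
        delta = b - (cy - piston_y)
        if delta > 0.0:
            f = kw * delta
            fy[i] += f
            tq[i] += -rx * f
            reaction += f
    return reaction


@njit(cache=True)
def _build_pair_list(pos, reach, L, W, head, nxt, buf, pairs_i, pairs_j):
    """Candidate pairs (i < j, ascending) within ``reach`` via a cell grid.

    The per-i candidates are sorted ascending so that force accumulation
    visits pairs in exactly the order of the all-pairs double loop.
    Returns the pair count, or -1 on buffer overflow.
    """
    n = pos.shape[0]
    hinv = 1.0 / reach
    ncx = max(1, int(L * hinv))
    ncy = max(1, int(W * hinv))
    # cell size is L/ncx >= reach (and likewise for y)
    cxw = ncx / L
    cyw = ncy / W
    for c in range(head.shape[0]):
        head[c] = -1
    for i in range(n):
        cxi = min(ncx - 1, max(0, int(pos[i, 0] * cxw)))
        cyi = min(ncy - 1, max(0, int(pos[i, 1] * cyw)))
        c = cyi * ncx + cxi
        nxt[i] = head[c]
        head[c] = i
    reach2 = reach * reach
    count = 0
    for i in range(n):
        cxi = min(ncx - 1, max(0, int(pos[i, 0] * cxw)))
        cyi = min(ncy - 1, max(0, int(pos[i, 1] * cyw)))
        m = 0
        for dy in range(-1, 2):
            yy = cyi + dy
            if yy < 0 or yy >= ncy:
                continue
            for dx in range(-1, 2):
                xx = cxi + dx
                if xx < 0 or xx >= ncx:
                    continue
                jj = head[yy * ncx + xx]
                while jj != -1:
                    if jj > i:
                        ddx = pos[i, 0] - pos[jj, 0]
                        ddy = pos[i, 1] - pos[jj, 1]
                        if ddx * ddx + ddy * ddy < reach2 and m < buf.shape[0]:
                            buf[m] = jj
                            m += 1
                    jj = nxt[jj]
        for u in range(1, m):
            key = buf[u]
            v = u - 1
            while v >= 0 and buf[v] > key:
                buf[v + 1] = buf[v]
                v -= 1
            buf[v + 1] = key
        if count + m > pairs_i.shape[0]:
            return -1
        for t in range(m):
            pairs_i[count] = i
            pairs_j[count] = buf[t]
            count += 1
    return count


@njit(cache=True)
def _compute_all_forces(pos, cth, sth, vel, omega, fx, fy, tq,
                        L, W, piston_y, a, b,
                        C, D, k, kw, cdamp, seed, degen_count,
                        use_pairs, pairs_i, pairs_j, n_pairs):
    """Fill force/torque arrays; returns total normal load on the piston."""
    n = pos.shape[0]
    for i in range(n):
        fx[i] = 0.0
        fy[i] = 0.0
        tq[i] = 0.0

    if use_pairs:
        for p in range(n_pairs):
            _pair_forces(pairs_i[p], pairs_j[p], pos, cth, sth, vel, omega,
                         fx, fy, tq, a, b, C, D, k, cdamp, seed, degen_count)
    else:
        for i in range(n):
            for j in range(i + 1, n):
                _pair_forces(i, j, pos, cth, sth, vel, omega, fx, fy, tq,
                             a, b, C, D, k, cdamp, seed, degen_count)

    piston_load = 0.0
    for i in range(n):
        piston_load += _wall_forces(i, pos, cth, sth, fx, fy, tq,
                                    L, W, piston_y, a, b, kw)
    return piston_load


@njit(cache=True)
def _simulate(pos, theta, vel, omega,
              L, W, a, b, mass, inertia,
              C, D, k, kw, cdamp, dt, lin_damp, ang_damp, gamma,
              piston_y0, piston_target, piston_speed,
              pressure_mode, piston_line_load, piston_mass,
              relax_tol, max_steps, fixed_steps, use_cells, seed):
    """Advance the world in place.

    Modes:
    * ``fixed_steps > 0`` — run exactly that many steps, piston stationary.
    * displacement mode — piston advances at ``piston_speed`` to
      ``piston_target`` then the crowd relaxes to the KE tolerance.
    * pressure mode — piston is a damped 1-DOF body under
      ``piston_line_load * L`` newtons; run until force balance + KE
      tolerance.

    Returns (status, steps, piston_y, kinetic_energy, bad_agent, degen_count).
    """
    n = pos.shape[0]
    fx = np.zeros(n)
    fy = np.zeros(n)
    tq = np.zeros(n)
    cth = np.empty(n)
    sth = np.empty(n)
    degen_count = np.zeros(1, dtype=np.int64)

    # Verlet pair list: rebuilt whenever anyone has moved more than skin/2,
    # which guarantees the force loop sees every pair within the cutoff and
    # therefore reproduces the all-pairs loop exactly.
    cutoff = max(D, 2.0 * a)
    skin = 0.1
    reach = cutoff + skin
    ncx = max(1, int(L / reach))
    ncy = max(1, int(W / reach))
    head = np.full(ncx * ncy, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    buf = np.empty(512, dtype=np.int64)
    max_pairs = 96 * n
    pairs_i = np.empty(max_pairs, dtype=np.int64)
    pairs_j = np.empty(max_pairs, dtype=np.int64)
    ref_pos = np.empty((n, 2))
    n_pairs = 0
    need_rebuild = True
    half_skin2 = (0.5 * skin) * (0.5 * skin)

    piston_y = piston_y0
    piston_v = 0.0
    total_load = piston_line_load * L
    keep = 1.0 - gamma
    lin_keep = 1.0 - lin_damp * dt
    ang_keep = 1.0 - ang_damp * dt

    steps = 0
    settled = 0
    ke = 0.0
    while True:
        moving = False
        if fixed_steps == 0 and not pressure_mode:
            if piston_y < piston_target:
                piston_y = piston_y + piston_speed * dt
                if piston_y > piston_target:
                    piston_y = piston_target
                moving = True

        if use_cells and need_rebuild:
            n_pairs = _build_pair_list(pos, reach, L, W, head, nxt, buf,
                                       pairs_i, pairs_j)
            if n_pairs < 0:
                return _PAIR_OVERFLOW, steps, piston_y, ke, -1, degen_count[0]
            ref_pos[:, :] = pos
            need_rebuild = False
        for i in range(n):
            cth[i] = math.cos(theta[i])
            sth[i] = math.sin(theta[i])
        piston_load = _compute_all_forces(
            pos, cth, sth, vel, omega, fx, fy, tq,
            L, W, piston_y, a, b, C, D, k, kw, cdamp, seed, degen_count,
            use_cells, pairs_i, pairs_j, n_pairs)

        ke = 0.0
        bad = -1
        inv_m_dt = dt / mass
        inv_i_dt = dt / inertia
        for i in range(n):
            vxi = (vel[i, 0] + fx[i] * inv_m_dt) * lin_keep * keep
            vyi = (vel[i, 1] + fy[i] * inv_m_dt) * lin_keep * keep
            vel[i, 0] = vxi
            vel[i, 1] = vyi
            pos[i, 0] += vxi * dt
            pos[i, 1] += vyi * dt
            wi = (omega[i] + tq[i] * inv_i_dt) * ang_keep * keep
            omega[i] = wi
            th = theta[i] + wi * dt
            th = th - math.floor(th / TWO_PI) * TWO_PI
            theta[i] = th
            ke += 0.5 * mass * (vxi * vxi + vyi * vyi) + 0.5 * inertia * wi * wi
            if not (math.isfinite(pos[i, 0]) and math.isfinite(pos[i, 1])
                    and math.isfinite(th)):
                bad = i
        if bad >= 0:
            return _NON_FINITE, steps + 1, piston_y, ke, bad, degen_count[0]
        if use_cells and not need_rebuild:
            for i in range(n):
                ddx = pos[i, 0] - ref_pos[i, 0]
                ddy = pos[i, 1] - ref_pos[i, 1]
                if ddx * ddx + ddy * ddy > half_skin2:
                    need_rebuild = True
                    break

        if pressure_mode:
            acc = (total_load - piston_load) / piston_mass
            piston_v = (piston_v + acc * dt) * keep
            piston_y += piston_v * dt
            if piston_y < 0.0:
                piston_y = 0.0
                piston_v = 0.0
            lim = 0.999 * W
            if piston_y > lim:
                piston_y = lim
                piston_v = 0.0
            ke += 0.5 * piston_mass * piston_v * piston_v

        steps += 1
        if fixed_steps > 0:
            if steps >= fixed_steps:
                return _OK, steps, piston_y, ke, -1, degen_count[0]
            continue

        at_target = pressure_mode or (piston_y >= piston_target)
        balanced = True
        if pressure_mode:
            balanced = abs(total_load - piston_load) < 0.01 * total_load
        if (not moving) and at_target and balanced and ke < relax_tol:
            settled += 1
            if settled >= SETTLE_WINDOW:
                return _OK, steps, piston_y, ke, -1, degen_count[0]
        else:
            settled = 0
        if steps >= max_steps:
            return _NO_CONVERGENCE, steps, piston_y, ke, -1, degen_count[0]


# ---------------------------------------------------------------------------
# python-level operations


def _run_kernel(state: WorldState, agent: AgentSpec, params: PhysicsParams, *,
                piston_target: float, pressure_mode: bool = False,
                fixed_steps: int = 0, max_steps: int | None = None,
                strict: bool = True) -> WorldState:
    params.validate_against(agent)
    new = state.copy()
    spec = state.scenario
    if max_steps is None:
        travel = 0
        if not pressure_mode and fixed_steps == 0:
            travel = int(
                math.ceil(
                    (piston_target - state.piston_displacement)
                    / (params.piston_speed * params.timestep_dt)
                )
            )
        max_steps = travel + params.max_relax_steps
    status, steps, piston_y, ke, bad, degen = _simulate(
        new.positions, new.orientations, new.velocities, new.angular_velocities,
        spec.length_L, spec.width_W, agent.semi_major, agent.semi_minor,
        agent.mass, agent.moment_of_inertia,
        params.repulsion_constant_C, params.neighbor_threshold_D,
        params.contact_stiffness_k, params.wall_stiffness_kw,
        params.contact_damping, params.timestep_dt,
        agent.linear_damping, agent.angular_damping, params.global_dissipation,
        state.piston_displacement, piston_target, params.piston_speed,
        pressure_mode, spec.piston_pressure, params.piston_mass,
        params.relax_tolerance, max_steps, fixed_steps,
        params.use_spatial_hash, np.int64(spec.rng_seed),
    )
    new.piston_displacement = float(piston_y)
    new.time = state.time + steps * params.timestep_dt
    if degen > 0:
        logger.warning("substituted seeded random contact normals %d times", degen)
    if status == _NON_FINITE:
        raise NonFiniteStateError(int(new.ids[bad]))
    if status == _PAIR_OVERFLOW:
        raise PhysicsError("neighbour pair list overflow (pathological density)")
    if status == _NO_CONVERGENCE and not strict:
        logger.info("settle horizon reached after %d steps (KE %.2e J)",
                    steps, ke)
        return new
    if status == _NO_CONVERGENCE and fixed_steps == 0:
        raise ConvergenceError(
            f"no equilibrium after {steps} steps "
            f"(residual kinetic energy {ke:.3e} J > {params.relax_tolerance} J)",
            residual_energy=ke,
        )
    logger.info(
        "kernel: %d steps, piston at %.3f m, residual KE %.2e J",
        steps, piston_y, ke,
    )
    return new


def step(state: WorldState, agent: AgentSpec, params: PhysicsParams,
         n_steps: int = 1) -> WorldState:
    """Advance exactly ``n_steps`` integration steps, piston stationary."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    return _run_kernel(
        state, agent, params,
        piston_target=state.piston_displacement,
        fixed_steps=n_steps, max_steps=n_steps,
    )


def relax(state: WorldState, agent: AgentSpec, params: PhysicsParams) -> WorldState:
    """Step with a stationary piston until total KE < relax_tolerance."""
    return _run_kernel(state, agent, params,
                       piston_target=state.piston_displacement)


def settle_packing(state: WorldState, agent: AgentSpec,
                   params: PhysicsParams) -> WorldState:
    """Pre-compression settle: resolve initial overlaps from the random
    orientations.

    Runs until the kinetic-energy tolerance or, failing that, for
    ``params.packing_settle_steps`` steps.  A loose, freshly packed crowd
    creeps for a long time on the nearly flat personal-space potential;
    that residual drift (sub-cm/s) is irrelevant to the compression
    measurements, which are all taken from strictly converged states after
    the piston moves, so this preparation phase does not error out on the
    step horizon.
    """
    return _run_kernel(state, agent, params,
                       piston_target=state.piston_displacement,
                       max_steps=params.packing_settle_steps, strict=False)


def compress_to(state: WorldState, target_displacement: float,
                agent: AgentSpec, params: PhysicsParams) -> WorldState:
    """Advance the piston to ``target_displacement`` and relax (quasi-static).

    Displacement-controlled mode: the piston plane travels at
    ``params.piston_speed`` and never retreats; afterwards the crowd is
    relaxed to the kinetic-energy tolerance.
    """
    if target_displacement < state.piston_displacement:
        raise ValueError(
            f"piston cannot retreat: target {target_displacement} < current "
            f"{state.piston_displacement}"
        )
    if target_displacement >= state.scenario.width_W:
        raise ValueError(
            f"target displacement {target_displacement} must be < width_W="
            f"{state.scenario.width_W}"
        )
    return _run_kernel(state, agent, params, piston_target=target_displacement)


def compress_pressure(state: WorldState, agent: AgentSpec,
                      params: PhysicsParams) -> WorldState:
    """Pressure-controlled compression: load the piston with
    ``piston_pressure * length_L`` newtons and integrate the coupled
    crowd+piston system until force balance; the settled displacement is in
    the returned state's ``piston_displacement``."""
    return _run_kernel(state, agent, params, piston_target=0.0,
                       pressure_mode=True)


def piston_reaction_force(state: WorldState, agent: AgentSpec,
                          params: PhysicsParams) -> float:
    """Total normal force (N) the crowd currently exerts on the piston."""
    return forces(state, agent, params)[2]


def forces(state: WorldState, agent: AgentSpec, params: PhysicsParams
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Instantaneous per-agent forces/torques and the piston load.

    Returns ``(force_xy (N,2), torque (N,), piston_load)`` — primarily a
    diagnostic/testing surface over the same kernel the integrator uses.
    """
    spec = state.scenario
    n = spec.n_agents
    pos = np.ascontiguousarray(state.positions)
    vel = np.ascontiguousarray(state.velocities)
    theta = state.orientations
    fx = np.zeros(n)
    fy = np.zeros(n)
    tq = np.zeros(n)
    cth = np.cos(theta)
    sth = np.sin(theta)
    degen = np.zeros(1, dtype=np.int64)
    D = params.neighbor_threshold_D
    reach = max(D, 2.0 * agent.semi_major)  # no skin needed for one shot
    ncx = max(1, int(spec.length_L / reach))
    ncy = max(1, int(spec.width_W / reach))
    head = np.full(ncx * ncy, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    buf = np.empty(512, dtype=np.int64)
    pairs_i = np.empty(96 * n, dtype=np.int64)
    pairs_j = np.empty(96 * n, dtype=np.int64)
    n_pairs = 0
    if params.use_spatial_hash:
        n_pairs = _build_pair_list(pos, reach, spec.length_L, spec.width_W,
                                   head, nxt, buf, pairs_i, pairs_j)
        if n_pairs < 0:
            raise PhysicsError("neighbour pair list overflow")
    load = _compute_all_forces(
        pos, cth, sth, vel, state.angular_velocities, fx, fy, tq,
        spec.length_L, spec.width_W, state.piston_displacement,
        agent.semi_major, agent.semi_minor,
        params.repulsion_constant_C, D,
        params.contact_stiffness_k, params.wall_stiffness_kw,
        params.contact_damping, np.int64(spec.rng_seed), degen,
        params.use_spatial_hash, pairs_i, pairs_j, n_pairs,
    )
    return np.column_stack([fx, fy]), tq, float(load)


# ---------------------------------------------------------------------------
# reference (oracle) implementations of the individual force laws


def repulsive_force(agent_i: AgentState, neighbors: Sequence[AgentState],
                    params: PhysicsParams) -> np.ndarray:
    """Total repulsion on one agent from its neighbour set.

    ``F_r = sum_j (p_i - p_j) * C * w_ij`` with
    ``w_ij = max(0, 1 - |p_i - p_j| / D)``.  Callers pass the agents within
    distance D; agents at or beyond D contribute nothing either way.  A
    coincident neighbour contributes zero force by the algebra (the
    difference vector vanishes) and is logged; the contact model's seeded
    random normal is what actually separates such a pair.
    """
    F = np.zeros(2)
    pi = agent_i.position
    C = params.repulsion_constant_C
    D = params.neighbor_threshold_D
    for other in neighbors:
        diff = pi - other.position
        d = float(np.hypot(diff[0], diff[1]))
        if d == 0.0:
            logger.warning(
                "agents %d and %d coincide; repulsion direction undefined",
                agent_i.id, other.id,
            )
            continue
        w = max(0.0, 1.0 - d / D)
        F += diff * (C * w)
    return F


def _contact_circles(agent: AgentState, spec: AgentSpec) -> np.ndarray:
    c, s = math.cos(agent.orientation), math.sin(agent.orientation)
    off = spec.circle_offset
    axis = np.array([c, s])
    return np.array([agent.position + k * off * axis for k in (-1, 0, 1)])


def contact_force_pair(a: AgentState, b_: AgentState, spec: AgentSpec,
                       params: PhysicsParams
                       ) -> tuple[np.ndarray, float, np.ndarray, float]:
    """Penalty contact between two agents via the 3-circle approximation.

    Returns ``(force_on_a, torque_on_a, force_on_b, torque_on_b)``;
    ``force_on_b`` is exactly ``-force_on_a``.
    """
    Fa = np.zeros(2)
    ta = 0.0
    tb = 0.0
    k = params.contact_stiffness_k
    cd = params.contact_damping
    r = spec.circle_radius
    ca = _contact_circles(a, spec)
    cb = _contact_circles(b_, spec)
    for pa in ca:
        for pb in cb:
            diff = pa - pb
            dist = float(np.hypot(diff[0], diff[1]))
            delta = 2.0 * r - dist
            if delta <= 0.0:
                continue
            if dist < 1.0e-12:
                logger.warning("coincident contact circles for agents %d/%d",
                               a.id, b_.id)
                n = np.array([1.0, 0.0])
            else:
                n = diff / dist
            pm = 0.5 * (pa + pb)
            ra = pm - a.position
            rb = pm - b_.position
            va = a.velocity + a.angular_velocity * np.array([-ra[1], ra[0]])
            vb = b_.velocity + b_.angular_velocity * np.array([-rb[1], rb[0]])
            closing = -float(np.dot(va - vb, n))
            fm = max(0.0, k * delta + cd * closing)
            f = fm * n
            Fa += f
            ta += ra[0] * f[1] - ra[1] * f[0]
            tb += -(rb[0] * f[1] - rb[1] * f[0])
    return Fa, ta, -Fa, tb


def wall_forces(state: WorldState, spec: AgentSpec, params: PhysicsParams
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-agent wall penalty forces/torques (reference implementation)."""
    sc = state.scenario
    n = sc.n_agents
    out_f = np.zeros((n, 2))
    out_t = np.zeros(n)
    kw = params.wall_stiffness_kw
    r = spec.circle_radius
    walls = [  # (point on plane, inward unit normal)
        (np.array([0.0, 0.0]), np.array([1.0, 0.0])),
        (np.array([sc.length_L, 0.0]), np.array([-1.0, 0.0])),
        (np.array([0.0, sc.width_W]), np.array([0.0, -1.0])),
        (np.array([0.0, state.piston_displacement]), np.array([0.0, 1.0])),
    ]
    for i, a in enumerate(state.agents):
        for c in _contact_circles(a, spec):
            for origin, normal in walls:
                delta = r - float(np.dot(c - origin, normal))
                if delta > 0.0:
                    f = kw * delta * normal
                    ra = c - a.position
                    out_f[i] += f
                    out_t[i] += ra[0] * f[1] - ra[1] * f[0]
    return out_f, out_t
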