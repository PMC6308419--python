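"""Agents, enclosures, and hexagonal initial packings.

A crowd is modelled in plan view: each person is an ellipse (shoulder line =
major axis) inside a rectangular enclosure with three fixed walls and one
movable "piston" wall.  The piston travels along the *width* direction (y);
the *length* direction (x) is parallel to the piston face.  Initial crowds
are laid out on a hexagonal lattice — rows of ``agents_per_row`` ellipses,
alternate rows shifted by half the intra-row spacing — which is the densest
safe packing for a standing crowd.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

TWO_PI = 2.0 * math.pi


class ScenarioError(ValueError):
    """Raised when a scenario specification is internally inconsistent."""


@dataclass(frozen=True)
class AgentSpec:
    """Fixed body parameters shared by every agent.

    The plan-view footprint is an ellipse with semi-axes ``semi_major``
    (half the shoulder width, 0.25 m) and ``semi_minor`` (half the chest
    depth, 0.125 m).  ``height`` is metadata only — the dynamics are 2D.
    Damping coefficients follow the convention that linear/angular velocity
    is multiplied by ``(1 - damping * dt)`` each step.
    """

    height: float = 1.7
    semi_major: float = 0.25
    semi_minor: float = 0.125
    mass: float = 50.0
    linear_damping: float = 0.0
    angular_damping: float = 0.05

    def __post_init__(self) -> None:
        if not (self.semi_major > self.semi_minor > 0.0):
            raise ScenarioError(
                f"require semi_major > semi_minor > 0, got "
                f"{self.semi_major} and {self.semi_minor}"
            )
        if self.mass <= 0.0:
            raise ScenarioError(f"mass must be positive, got {self.mass}")
        if self.linear_damping < 0.0 or self.angular_damping < 0.0:
            raise ScenarioError("damping coefficients must be >= 0")

    @property
    def footprint_area(self) -> float:
        """Plan-view area of one agent, pi*a*b (m^2)."""
        return math.pi * self.semi_major * self.semi_minor

    @property
    def moment_of_inertia(self) -> float:
        """Moment of inertia of a uniform ellipse about its center (kg m^2)."""
        return self.mass * (self.semi_major**2 + self.semi_minor**2) / 4.0

    @property
    def circle_offset(self) -> float:
        """Offset of the outer contact circles along the major axis (m)."""
        return self.semi_major - self.semi_minor

    @property
    def circle_radius(self) -> float:
        """Radius of the three contact circles (= semi_minor, m)."""
        return self.semi_minor


@dataclass
class AgentState:
    """Evolving pose and velocity of one agent (plan view, SI units)."""

    id: int
    position: np.ndarray
    orientation: float
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(2))
    angular_velocity: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(2).copy()
        self.velocity = np.asarray(self.velocity, dtype=float).reshape(2).copy()
        if not np.all(np.isfinite(self.position)):
            raise ScenarioError(f"agent {self.id}: non-finite position")
        self.orientation = float(self.orientation) % TWO_PI


@dataclass(frozen=True)
class ScenarioSpec:
    """Enclosure geometry, population, packing layout, and piston protocol.

    ``length_L`` runs parallel to the piston face; ``width_W`` is the
    direction the piston travels.  ``piston_schedule`` lists the piston
    displacements (m, strictly increasing) at which the crowd state is
    recorded.  ``piston_pressure`` is the line load (N per metre of wall)
    used in pressure-controlled compression.
    """

    n_agents: int
    length_L: float
    width_W: float
    agents_per_row: int
    piston_schedule: tuple[float, ...] = ()
    piston_pressure: float = 4450.0
    rng_seed: int = 0
    wall_margin: float = 0.135

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "piston_schedule", tuple(float(d) for d in self.piston_schedule)
        )
        if self.n_agents < 1 or self.agents_per_row < 1:
            raise ScenarioError("n_agents and agents_per_row must be >= 1")
        if self.n_agents % self.agents_per_row != 0:
            raise ScenarioError(
                f"population of {self.n_agents} agents does not divide into "
                f"rows of {self.agents_per_row}"
            )
        if self.length_L <= 0.0 or self.width_W <= 0.0:
            raise ScenarioError(
                f"enclosure dimensions must be positive, got "
                f"{self.length_L} x {self.width_W}"
            )
        if self.wall_margin <= 0.0:
            raise ScenarioError("wall_margin must be positive")
        sched = self.piston_schedule
        if any(d <= 0.0 or d >= self.width_W for d in sched):
            raise ScenarioError(
                f"every scheduled displacement must lie in (0, width_W="
                f"{self.width_W}), got {sched}"
            )
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ScenarioError(f"schedule must be strictly increasing: {sched}")
        if self.piston_pressure <= 0.0:
            raise ScenarioError("piston_pressure must be positive")

    @property
    def n_rows(self) -> int:
        return self.n_agents // self.agents_per_row

    @property
    def row_pitch(self) -> float:
        """Vertical spacing between lattice rows (m)."""
        return self.width_W / self.n_rows

    @property
    def intra_row_spacing(self) -> float:
        """Horizontal center spacing within a row (m)."""
        return (self.length_L - 2.0 * self.wall_margin) / self.agents_per_row

    @property
    def area(self) -> float:
        return self.length_L * self.width_W


#: The three study scenarios: equal starting density (~7.0-7.4 people/m^2),
#: 20 agents per row, and progressively longer piston protocols.
PRESETS: dict[str, dict] = {
    "crowd200": dict(
        n_agents=200, length_L=10.27, width_W=2.76, agents_per_row=20,
        piston_schedule=(0.5, 1.0, 1.5, 2.0),
    ),
    "crowd300": dict(
        n_agents=300, length_L=10.27, width_W=4.01, agents_per_row=20,
        piston_schedule=(0.5, 1.0, 1.5, 2.0, 2.5),
    ),
    "crowd400": dict(
        n_agents=400, length_L=10.27, width_W=5.28, agents_per_row=20,
        piston_schedule=(0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5),
    ),
}


def preset(name: str, rng_seed: int = 0) -> ScenarioSpec:
    """Return one of the built-in scenarios (``crowd200/300/400``)."""
    try:
        kwargs = PRESETS[name]
    except KeyError:
        raise ScenarioError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    return ScenarioSpec(rng_seed=rng_seed, **kwargs)


def hex_pack_arrays(
    spec: ScenarioSpec, agent: AgentSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Hexagonal lattice positions and seeded random orientations.

    Returns ``(positions, orientations)`` as arrays of shape (N, 2) and (N,).
    Rows are filled bottom-to-top, left-to-right; odd rows are shifted right
    by half the intra-row spacing.  Positions depend only on the geometry;
    orientations are drawn uniformly from [0, 2*pi) with ``spec.rng_seed``.
    """
    agent = agent or AgentSpec()
    s = spec.intra_row_spacing
    pitch = spec.row_pitch
    margin = spec.wall_margin
    if s <= 0.0:
        raise ScenarioError(
            f"enclosure length {spec.length_L} m leaves no room for "
            f"{spec.agents_per_row} agents with wall margin {margin} m"
        )

    cols = np.arange(spec.agents_per_row)
    rows = np.arange(spec.n_rows)
    x0 = margin + (cols + 0.5) * s
    positions = np.empty((spec.n_agents, 2))
    for r in rows:
        x = x0 + (0.5 * s if r % 2 == 1 else 0.0)
        y = (r + 0.5) * pitch
        sl = slice(r * spec.agents_per_row, (r + 1) * spec.agents_per_row)
        positions[sl, 0] = x
        positions[sl, 1] = y

    b = agent.semi_minor
    if (
        positions[:, 0].min() < b
        or positions[:, 0].max() > spec.length_L - b
        or positions[:, 1].min() < b
        or positions[:, 1].max() > spec.width_W - b
    ):
        raise ScenarioError(
            "lattice overflows the enclosure: centers must clear every wall "
            f"by semi_minor={b} m; need length >= "
            f"{2 * b + (spec.agents_per_row + 0.5) * s - s:.3f} m and width >= "
            f"{2 * b * spec.n_rows:.3f} m (got {spec.length_L} x {spec.width_W})"
        )

    rng = np.random.default_rng(spec.rng_seed)
    orientations = rng.uniform(0.0, TWO_PI, spec.n_agents)
    return positions, orientations


def hex_pack(spec: ScenarioSpec, agent: AgentSpec | None = None) -> list[AgentState]:
    """Generate the initial hexagonally packed crowd as AgentState objects."""
    positions, orientations = hex_pack_arrays(spec, agent)
    return [
        AgentState(id=i, position=positions[i], orientation=orientations[i])
        for i in range(spec.n_agents)
    ]


def initial_global_density(spec: ScenarioSpec) -> float:
    """Whole-enclosure density n_agents / (L * W), people per m^2."""
    if spec.area <= 0.0:
        raise ScenarioError("enclosure area must be positive")
    return spec.n_agents / spec.area


# ---------------------------------------------------------------------------
# Config and layout I/O


def scenario_from_mapping(mapping: Mapping) -> ScenarioSpec:
    """Build a ScenarioSpec from a config mapping (YAML/JSON keys)."""
    known = {f.name for f in dataclasses.fields(ScenarioSpec)}
    unknown = set(mapping) - known
    if unknown:
        raise ScenarioError(
            f"unknown scenario keys {sorted(unknown)}; valid keys: {sorted(known)}"
        )
    return ScenarioSpec(**mapping)


def load_scenario_config(path: str | Path) -> dict:
    """Load a scenario config file (YAML or JSON) into a dict.

    The file holds ScenarioSpec keys at top level, with optional ``physics``
    and ``raster`` sub-mappings for overrides.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if not isinstance(data, Mapping):
        raise ScenarioError(f"config {path} must be a mapping, got {type(data)}")
    return dict(data)


def write_layout_csv(agents: Iterable[AgentState], path: str | Path) -> None:
    """Write agent poses as CSV with columns id, x, y, theta."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "x", "y", "theta"])
        for a in agents:
            writer.writerow(
                [a.id, repr(float(a.position[0])), repr(float(a.position[1])),
                 repr(float(a.orientation))]
            )


def read_layout_csv(path: str | Path) -> list[AgentState]:
    """Read a layout CSV written by :func:`write_layout_csv`."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                AgentState(
                    id=int(row["id"]),
                    position=np.array([float(row["x"]), float(row["y"])]),
                    orientation=float(row["theta"]),
                )
            )
    return out
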