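import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crowdcrush import AgentSpec, PhysicsParams, ScenarioSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=20,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def agent() -> AgentSpec:
    return AgentSpec()


@pytest.fixture(scope="session")
def params() -> PhysicsParams:
    return PhysicsParams()


@pytest.fixture
def tiny_spec() -> ScenarioSpec:
    """Six agents in a 3 m x 1.2 m box — fast to relax and compress."""
    return ScenarioSpec(
        n_agents=6, length_L=3.0, width_W=1.2, agents_per_row=3,
        piston_schedule=(0.15, 0.3), rng_seed=7,
    )


def random_world(n: int, seed: int, box=(4.0, 2.0), crammed: bool = False):
    """A seeded random WorldState for property tests.

    ``crammed`` packs everyone into a 1 m^2 patch to exercise heavy overlap.
    """
    from crowdcrush.physics import WorldState

    rng = np.random.default_rng(seed)
    L, W = box
    spec = ScenarioSpec(n_agents=n, length_L=L, width_W=W, agents_per_row=n,
                        rng_seed=seed, wall_margin=0.01)
    if crammed:
        pos = rng.uniform([L / 2 - 0.5, W / 2 - 0.5], [L / 2 + 0.5, W / 2 + 0.5],
                          (n, 2))
    else:
        pos = rng.uniform([0.4, 0.4], [L - 0.4, W - 0.4], (n, 2))
    return WorldState(
        scenario=spec,
        ids=np.arange(n),
        positions=pos,
        orientations=rng.uniform(0.0, 2 * np.pi, n),
        velocities=rng.normal(0.0, 0.1, (n, 2)),
        angular_velocities=rng.normal(0.0, 0.1, n),
    )
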