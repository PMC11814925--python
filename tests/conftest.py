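import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from remapkit._rng import rng_for
from remapkit.synthetic import ArenaSpec, TrajectoryParams, simulate_trajectory

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def arena():
    return ArenaSpec()


@pytest.fixture(scope="session")
def foraging_track(arena):
    """One 600 s foraging trajectory shared across read-only tests."""
    return simulate_trajectory(arena, TrajectoryParams(), rng_for(42, "track"))


@pytest.fixture(scope="session")
def stationary_track(arena):
    """A fully immobile 600 s session (pot-rest analogue)."""
    params = TrajectoryParams(duration=600.0, mean_speed=0.0, speed_sd=0.0,
                              immobility_bout_rate=0.0)
    return simulate_trajectory(arena, params, rng_for(43, "track"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
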