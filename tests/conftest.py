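import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import glycopmf as g

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_windows():
    """Default synthetic umbrella dataset (42 windows, master seed 1)."""
    return g.generate_umbrella_dataset(seed=1)


@pytest.fixture(scope="session")
def default_profile(default_windows):
    return g.wham(default_windows)


@pytest.fixture(scope="session")
def default_landmarks(default_profile):
    return g.landmarks(default_profile, (1.3, 1.9), (2.9, 3.5))


@pytest.fixture(scope="session")
def second_profile():
    """Independently seeded replica of the default reconstruction (seed 2)."""
    return g.wham(g.generate_umbrella_dataset(seed=2))


@pytest.fixture(scope="session")
def default_ring_trajectory():
    """Default synthetic ring trajectory sweeping RC2 across the reaction."""
    rc2 = np.linspace(1.4, 3.3, 2000)
    frames = g.generate_ring_trajectory(g.DEFAULT_PUCKER_PATH, rc2, seed=1)
    return rc2, frames


@pytest.fixture(scope="session")
def default_itinerary(default_ring_trajectory):
    rc2, frames = default_ring_trajectory
    ring = ("O5", "C1", "C2", "C3", "C4", "C5")
    puckers = [g.cremer_pople(fr.positions(ring)) for fr in frames]
    return g.itinerary(puckers, rc2)
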