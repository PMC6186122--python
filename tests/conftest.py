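import numpy as np
import pytest

from dops.controller import DOPSConfig
from dops.objective import BoundsBox, ObjectiveSpec
from dops.swarm import SwarmSettings


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sphere_spec():
    """2-D sphere shifted off the origin, on [-10, 10]^2."""
    center = np.array([3.0, -2.0])

    def sphere(x):
        return float(np.sum((x - center) ** 2))

    return ObjectiveSpec(
        name="shifted-sphere-2d",
        evaluate=sphere,
        bounds=BoundsBox.cube(-10.0, 10.0, 2),
    )


@pytest.fixture
def small_config():
    """A cheap configuration for mechanical checks (8 particles, 2 sub-swarms)."""
    return DOPSConfig(
        total_budget=400,
        swarm=SwarmSettings(n_particles=8, n_subswarms=2),
        seed=7,
    )
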