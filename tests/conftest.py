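import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rombergsway as rs

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_config():
    """A fast 4 s cohort config for structural tests."""
    return rs.CohortConfig(
        n_per_group=2, group_labels=("HC", "BVH"), duration=4.0, seed=7
    )


@pytest.fixture
def study_config():
    """The full 30 s / 128 Hz trial shape of the protocol."""
    return rs.CohortConfig(n_per_group=2, group_labels=("HC", "BVH"), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
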