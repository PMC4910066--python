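import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def simulated_family():
    """A seeded single-duplication family used across modules."""
    from ddrclock.simulate import SimConfig, simulate_family

    return simulate_family(
        SimConfig(seed=7, repeat_length=2000, n_species=6)
    )
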