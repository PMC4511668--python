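import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """Small, fast configuration used across unit tests."""
    from micronull import SimulationConfig

    return SimulationConfig(
        num_hosts=30,
        slots_per_host=60,
        num_taxa=8,
        parental_fraction=0.4,
        pooled_env_fraction=0.2,
        max_generations=120,
        record_interval=40,
        seed=99,
    )
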