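import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_study():
    """Small seeded synthetic study shared by pipeline-level tests."""
    from ibrtox import EffectConfig, generate_study

    return generate_study(EffectConfig(n_per_cell=5, seed=7))


@pytest.fixture
def small_viability():
    from ibrtox import ViabilityConfig, generate_viability

    return generate_viability(ViabilityConfig(n_per_cell=5), 7)
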