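import pytest
from hypothesis import HealthCheck, settings

from abivr import SimScenario, simulate_two_samples

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def midsize_scenario():
    """Scaled-down confounding-free study used across module tests."""
    return SimScenario(n_sample1=8_000, n_sample2=1_000, seed=1234)


@pytest.fixture(scope="session")
def midsize_study(midsize_scenario):
    return simulate_two_samples(midsize_scenario)
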