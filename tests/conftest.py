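import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from capdyn.synthetic import SceneConfig, simulate_cap_movie

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_movie():
    """One default wild-type movie with ground truth, shared across tests."""
    config = SceneConfig(seed=11)
    stack, truth = simulate_cap_movie(config)
    return config, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
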