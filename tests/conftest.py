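import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitoshift.simulate import SimConfig, make_mitogenome

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset():
    """One fully featured synthetic mitogenome shared across test modules."""
    genome, models, truth = make_mitogenome(SimConfig(seed=7))
    return genome, models, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
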