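import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_flora():
    """Three species in one region: Apr-Jun, May-May, and a Nov-Feb wrap."""
    from mdephen import FloweringRecord

    return [
        FloweringRecord("sp1", "regA", "woody", 4, 6),
        FloweringRecord("sp2", "regA", "herbaceous", 5, 5),
        FloweringRecord("sp3", "regA", "herbaceous", 11, 2),
    ]
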