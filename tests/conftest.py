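import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def cylinder_phantom():
    """50 mm cylinder with exact circular CSA pi * 4^2 mm^2 (2.513 ml)."""
    from tendonmech import synthgen

    return synthgen.make_phantom(50.0, ("constant", np.pi * 16.0))


@pytest.fixture
def default_subject():
    from tendonmech import synthgen

    return synthgen.SimulatedSubject()


@pytest.fixture
def crossover_dataset():
    from tendonmech import synthgen

    return synthgen.simulate_crossover_dataset(16, seed=42)
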