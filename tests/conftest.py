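import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20200616)


@pytest.fixture
def small_scene():
    """A modest DAPI/gamma scene with fixed foci counts and no touching pairs."""
    import slicequant as sq

    dapi, gamma, truth = sq.generate_foci_scene(
        6,
        ("fixed", 9),
        foci_sigma=2.0,
        noise_level=0.02,
        seed=42,
        shape=(256, 256),
    )
    return dapi, gamma, truth
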