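import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def infinite_geom():
    from neonirs import AcquisitionGeometry

    return AcquisitionGeometry(geometry="infinite")


@pytest.fixture
def semi_geom():
    from neonirs import AcquisitionGeometry

    return AcquisitionGeometry(geometry="semi_infinite")
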