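import numpy as np
import pytest
from hypothesis import settings

from remotetae import LayoutGeometry, ObserverParams, OrientationField, test_location

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def concentric():
    return OrientationField("concentric")


@pytest.fixture
def linear5():
    """Horizontal rate-5 gradient anchored at the test site at +15 deg."""
    return OrientationField(
        "linear_gradient",
        gradient_rate=5.0,
        axis="horizontal",
        anchor_point=test_location(),
        anchor_orientation=15.0,
    )


@pytest.fixture
def proximal_953():
    return LayoutGeometry(noise_layout="proximal", annulus_outer_radius=9.53)


@pytest.fixture
def observer():
    return ObserverParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
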