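import numpy as np
import pytest

from arterymech.kinematics import ReferenceGeometry
from arterymech.wall_mechanics import default_model, WallQuadrature


@pytest.fixture(scope="session")
def geom():
    return ReferenceGeometry(r_outer=4.0, r_inner=3.0, opening_angle=1.571,
                             length_ref=10.0)


@pytest.fixture(scope="session")
def model():
    """Packaged default model at full quadrature resolution."""
    return default_model()


@pytest.fixture(scope="session")
def fast_model():
    """Default model at the reduced resolution used inside optimization."""
    return default_model(WallQuadrature(16, 8, 8))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
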