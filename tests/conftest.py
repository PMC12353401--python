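import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def affine_displacement():
    """Factory for affine displacement fields u = a + b*x + c*y (same for v)."""
    from stretchlab import DisplacementField

    def make(shape, ux=(0.0, 0.0, 0.0), vy=(0.0, 0.0, 0.0)):
        H, W = shape
        y, x = np.mgrid[0:H, 0:W].astype(float)
        u = ux[0] + ux[1] * x + ux[2] * y
        v = vy[0] + vy[1] * x + vy[2] * y
        return DisplacementField(u, v)

    return make
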