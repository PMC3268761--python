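import numpy as np
import pytest

from polarsim.geometry import GridKind, make_grid


@pytest.fixture(scope="session")
def circle_grid():
    return make_grid(GridKind.CIRCLE, 64, 2.0)


@pytest.fixture(scope="session")
def sphere_grid():
    return make_grid(GridKind.AXISYMMETRIC_SPHERE, 64, 2.0)


@pytest.fixture(params=["circle", "axisymmetric_sphere"])
def any_grid(request):
    return make_grid(request.param, 64, 2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
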