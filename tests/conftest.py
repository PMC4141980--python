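import numpy as np
import pytest

from neodot.haemoglobin import default_extinction_table
from neodot.head_forward import (
    build_jacobian_set,
    make_layer_mesh,
    place_optodes_hemisphere,
    stack_multispectral,
)


@pytest.fixture(scope="session")
def hemi_probe():
    return place_optodes_hemisphere()


@pytest.fixture(scope="session")
def hemi_mesh():
    return make_layer_mesh(seed=0)


@pytest.fixture(scope="session")
def hemi_jset(hemi_mesh, hemi_probe):
    return build_jacobian_set(hemi_mesh, hemi_probe)


@pytest.fixture(scope="session")
def stacked_S(hemi_jset):
    return stack_multispectral(hemi_jset, default_extinction_table())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
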