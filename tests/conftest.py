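import numpy as np
import pytest

from prestim.inverse import HeadModel, build_source_space, compute_leadfield
from prestim.synthetic import make_montage, make_templates


@pytest.fixture(scope="session")
def montage16():
    return make_montage(16, seed=3)


@pytest.fixture(scope="session")
def montage64():
    return make_montage(64, seed=5)


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def source_space(head):
    return build_source_space(head, spacing=0.25)


@pytest.fixture(scope="session")
def leadfield64(montage64, head, source_space):
    return compute_leadfield(montage64, head, source_space)


@pytest.fixture(scope="session")
def templates64(montage64, leadfield64):
    return make_templates(montage64, 3, leadfield64, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
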