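import numpy as np
import pytest

from gofrust.energy import ModelParameters
from gofrust.fixtures import ToyProteinSpec, make_toy_hairpin
from gofrust.structures import build_frustration_set, build_topology


@pytest.fixture(scope="session")
def hairpin():
    return make_toy_hairpin(ToyProteinSpec())


@pytest.fixture(scope="session")
def topology(hairpin):
    return build_topology(hairpin)


@pytest.fixture(scope="session")
def frustration(hairpin, topology):
    return build_frustration_set(hairpin, topology)


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def params_frustrated():
    return ModelParameters(frustration_enabled=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
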