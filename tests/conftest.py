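import numpy as np
import pytest

import isakernel as ik


@pytest.fixture(scope="session")
def params_i125():
    return ik.load_params("I125_6702")


@pytest.fixture(scope="session")
def params_ir192():
    return ik.load_params("Ir192_Flexisource")


@pytest.fixture(scope="session")
def seed_6702():
    return ik.build_6702()


@pytest.fixture(scope="session")
def seed_flexi():
    return ik.build_flexisource()


@pytest.fixture(scope="session")
def spectrum_i125():
    return ik.load_spectrum("I125_6702")


@pytest.fixture(scope="session")
def spectrum_ir192():
    return ik.load_spectrum("Ir192_Flexisource")


@pytest.fixture(scope="session")
def water():
    return ik.get_material("water")


@pytest.fixture
def rng():
    return np.random.default_rng(20130506)
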