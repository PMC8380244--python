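import numpy as np
import pytest
from hypothesis import settings

# reproducible property tests: same example stream on every run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from alumtk.physiology import reference_for
from alumtk.model import default_parameters


@pytest.fixture(scope="session")
def human_male():
    return reference_for("human", "male")


@pytest.fixture(scope="session")
def human_female():
    return reference_for("human", "female")


@pytest.fixture(scope="session")
def rat_young():
    return reference_for("rat", 0.25)


@pytest.fixture(scope="session")
def rat_old():
    return reference_for("rat", 0.48)


@pytest.fixture(scope="session")
def all_references(human_male, human_female, rat_young, rat_old):
    return [human_male, human_female, rat_young, rat_old]


@pytest.fixture(scope="session")
def hm_params(human_male):
    return default_parameters(human_male)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
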