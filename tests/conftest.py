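import numpy as np
import pytest

from seedpattern.model import MultiLocusGenotype, default_model
from seedpattern.segregation import PopulationDesign
from seedpattern.synth import TABLE1_FOUNDERS


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def magic_parents():
    return [MultiLocusGenotype.from_string(s) for s in TABLE1_FOUNDERS.values()]


@pytest.fixture(scope="session")
def magic_design(magic_parents):
    return PopulationDesign("MAGIC", magic_parents)


def g(text: str) -> MultiLocusGenotype:
    return MultiLocusGenotype.from_string(text)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
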