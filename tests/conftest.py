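import numpy as np
import pytest

from trastuzumab_cea.parameters import LifeTable, ParameterSet
from trastuzumab_cea.profiles import calibrated


@pytest.fixture
def default_params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture
def flat_life_table() -> LifeTable:
    """Constant 1% annual background mortality, ages 50-100."""
    ages = range(50, 101)
    return LifeTable(ages, [0.01] * len(list(ages)))


@pytest.fixture
def zero_life_table() -> LifeTable:
    return LifeTable(range(50, 101), [0.0] * 51)


@pytest.fixture(scope="session")
def profile():
    """Frozen calibrated profile: (ParameterSet, LifeTable)."""
    return calibrated()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
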