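import numpy as np
import pytest

from tidemarsh.accretion import SETTLING_VELOCITY_DEFAULT, DepositionLookup
from tidemarsh.fixtures import ToyBaySpec, make_toy_bay
from tidemarsh.tides import compute_datums, generate_tidal_month


@pytest.fixture(scope="session")
def tide():
    return generate_tidal_month()


@pytest.fixture(scope="session")
def datums(tide):
    return compute_datums(tide)


@pytest.fixture(scope="session")
def lookup(tide):
    """Deposition lookup at the calibrated default settling velocity."""
    return DepositionLookup(tide, SETTLING_VELOCITY_DEFAULT)


@pytest.fixture(scope="session")
def toy_bay():
    return make_toy_bay(ToyBaySpec(seed=0))


@pytest.fixture(scope="session")
def small_bay():
    """A smaller toy bay for pipeline-level tests."""
    return make_toy_bay(ToyBaySpec(nrows=60, ncols=60, seed=1))
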