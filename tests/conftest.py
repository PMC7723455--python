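import numpy as np
import pytest

from spinorder import MASCondition, PowderScheme, fslg, one_bond_ch

#: Order parameters reported for the receptor's Met/Arg/His regions across
#: the three excitation conditions; used as the round-trip grid.
REPORTED_S = (0.17, 0.34, 0.41, 0.46, 0.47, 0.50, 0.61, 0.67,
              0.80, 0.81, 0.83, 0.85, 0.87, 0.90, 0.91)


@pytest.fixture(scope="session")
def pair():
    return one_bond_ch()


@pytest.fixture(scope="session")
def scale():
    return fslg()


@pytest.fixture(scope="session")
def mas9():
    return MASCondition.evenly_spaced(5000.0, 9)


@pytest.fixture(scope="session")
def mas7():
    return MASCondition.evenly_spaced(5000.0, 7)


@pytest.fixture(scope="session")
def powder():
    # shared so the unit-phase / scan-library caches persist across tests
    return PowderScheme()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
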