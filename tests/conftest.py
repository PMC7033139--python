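import numpy as np
import pytest

from tmesim.biochem import CRParams, GrowthFactorParams
from tmesim.grid import BoundaryCondition, LatticeSpec, ScalarField


@pytest.fixture
def lat9():
    return LatticeSpec(9, 9, 9, 50.0)


@pytest.fixture
def lat7():
    return LatticeSpec(7, 7, 7, 10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cr():
    return CRParams()


@pytest.fixture
def gf():
    return GrowthFactorParams()


@pytest.fixture
def zero_bc():
    return BoundaryCondition(0.0)


@pytest.fixture
def random_field():
    def make(lattice, rng, lo=0.0, hi=1.0, name="f"):
        return ScalarField(lattice, rng.uniform(lo, hi, lattice.shape), name)
    return make
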