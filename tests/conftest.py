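import numpy as np
import pytest

from presyn import FusionKinetics, SNAREEnergetics, VesiclePools


@pytest.fixture
def kin():
    return FusionKinetics(N=2, k1=1.0, k2=0.01)


@pytest.fixture
def pools():
    return VesiclePools(ntot1=100.0, ntot2=200.0)


@pytest.fixture
def energetics():
    return SNAREEnergetics(dG=20.0, nCa=4.0, k0=0.01, ca0=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
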