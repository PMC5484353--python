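import numpy as np
import pytest

from boast31p import PoolSystem


@pytest.fixture
def cardiac_pools() -> PoolSystem:
    """Myocardial two-pool system: [PCr]:[ATP]=1.5, T1*=6.0/2.0 s, kf=0.32."""
    return PoolSystem()


@pytest.fixture
def unit_pools() -> PoolSystem:
    """Same relaxation and exchange but with m0_pcr normalised to 1."""
    return PoolSystem(m0_pcr=1.0, m0_atp=1.0 / 1.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
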