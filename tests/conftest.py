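import numpy as np
import pytest
from dataclasses import replace

from vesiclesaxs.model import QGrid, StackSpec
from vesiclesaxs.synthetic import NoiseModel, generate_curve, preset


@pytest.fixture(scope="session")
def default_grid():
    return QGrid.default()


@pytest.fixture(scope="session")
def etho_wi():
    return preset("ETHO_WI").model


@pytest.fixture(scope="session")
def etho_ei():
    return preset("ETHO_EI").model


@pytest.fixture(scope="session")
def lipo_ei():
    return preset("LIPO_EI").model


@pytest.fixture(scope="session")
def etho_wi_bragg(etho_wi):
    """ETHO_WI variant with the repeat spacing set to the observed 7.22 nm."""
    return replace(etho_wi, stack=replace(etho_wi.stack, c=7.22))


@pytest.fixture()
def noiseless():
    """Noise model whose floor perturbation vanishes in double precision."""
    return NoiseModel(relative_sigma=0.0, sigma_floor=1e-300)


@pytest.fixture(scope="session")
def etho_wi_curve(etho_wi_bragg):
    return generate_curve(etho_wi_bragg, seed=11)
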