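import numpy as np
import pytest

from emtcircuits.circuits import build_core_emt, extend_with_psf
from emtcircuits.params import ParameterSet


@pytest.fixture(scope="session")
def params():
    return ParameterSet.baseline()


@pytest.fixture(scope="session")
def core_circuit(params):
    return build_core_emt(params)


@pytest.fixture(scope="session")
def grhl2_circuit(params, core_circuit):
    return extend_with_psf(core_circuit, "grhl2", params=params)


@pytest.fixture(scope="session")
def tristable_core(params):
    """Core circuit at a SNAIL level inside its three-state region."""
    return build_core_emt(params, snail=198e3)


@pytest.fixture(scope="session")
def core_sweep_grid():
    return np.linspace(120e3, 300e3, 46)


@pytest.fixture(scope="session")
def psf_sweep_grid():
    return np.linspace(120e3, 900e3, 66)
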