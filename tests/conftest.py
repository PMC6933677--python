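import numpy as np
import pytest

from celldiv import ModelParams, default_time_grid, fsp_propagate

LN2 = np.log(2.0)


@pytest.fixture(scope="session")
def params():
    """Canonical dimensionless setup: mu = k = ln2, s0 = 1 => tau = 1, theta = 1."""
    return ModelParams()


@pytest.fixture(scope="session")
def grid7(params):
    return default_time_grid(params, 7)


@pytest.fixture(scope="session")
def dist7(params, grid7):
    """FSP solution at theta = 1 on [0, 7 tau], truncation comfortably deep."""
    return fsp_propagate(params, 20, grid7)
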