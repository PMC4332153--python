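import numpy as np
import pytest

from camprelay import CellParams
from camprelay.model import resting_state


@pytest.fixture(scope="session")
def params():
    """Default single-cell parameters (the study's values)."""
    return CellParams()


@pytest.fixture(scope="session")
def det_params(params):
    """Deterministic (sigma = 0) variant of the defaults."""
    from dataclasses import replace
    return replace(params, sigma=0.0)


@pytest.fixture(scope="session")
def rest(det_params):
    """Resting fixed point at zero external cAMP."""
    return resting_state(det_params, 0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
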