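import numpy as np
import pytest

from icam.model import ModelParams

#: Canonical detector response measured for the instrument the model
#: emulates: 0.163 V mean and 0.097 V sd per secondary electron.
C_MU = 0.163
C_SIGMA = 0.097


@pytest.fixture
def rng():
    return np.random.default_rng(20240708)


@pytest.fixture
def gold_params():
    """Gold-like operating point: eta=2.75 at dose 21 ions/pixel."""
    return ModelParams(dose=21.0, yield_eta=2.75, c_mu=C_MU, c_sigma=C_SIGMA)


@pytest.fixture
def silicon_params():
    """Silicon-like operating point: eta=1.82 at dose 21 ions/pixel."""
    return ModelParams(dose=21.0, yield_eta=1.82, c_mu=C_MU, c_sigma=C_SIGMA)
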