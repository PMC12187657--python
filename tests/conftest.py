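import numpy as np
import pytest

from brcascreen import default_parameters


@pytest.fixture
def defaults():
    return default_parameters()


@pytest.fixture
def compat(defaults):
    """Base case under the published-QALY-compatible FH wiring."""
    return defaults.replace(fh_detection_convention="paper_compat")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
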