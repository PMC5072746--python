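import numpy as np
import pytest

from itquant import OrdinalConfig, TimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture
def toy_pdf():
    """Half-half two-pattern PDF over N=6 states (D=3)."""
    return np.array([0.5, 0.5, 0.0, 0.0, 0.0, 0.0])


@pytest.fixture
def ramp():
    return TimeSeries(np.arange(200, dtype=float))


@pytest.fixture
def cfg_unweighted():
    return OrdinalConfig(D=3, tau=1, weighted=False)
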