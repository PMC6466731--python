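import numpy as np
import pytest

from retinoscope import ComponentParams, TraceConfig, make_default_stimulus


@pytest.fixture(scope="session")
def stimulus():
    return make_default_stimulus()


@pytest.fixture(scope="session")
def config():
    return TraceConfig()


@pytest.fixture
def clean_params():
    """Deterministic a+b waveform only: no OPs, no mains, no noise."""
    return ComponentParams(op_amp_uV=0.0, mains_amp_uV=0.0, noise_sd_uV=0.0)


@pytest.fixture
def op_only_params():
    """Isolated OP packet: no a/b waves, no mains, no noise."""
    return ComponentParams(a_Vmax_uV=0.0, b_Vmax_uV=0.0, mains_amp_uV=0.0, noise_sd_uV=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
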