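import numpy as np
import pytest

from dibperm import synth


@pytest.fixture(scope="session")
def noiseless_control_series():
    """Noiseless droplet-pair series at the pure-DOPC control permeability."""
    obs, truth = synth.gen_dib_series(
        synth.dib_preset("dopc_control", seed=0, radius_noise_sd=0.0)
    )
    return obs, truth


@pytest.fixture(scope="session")
def control_thermogram():
    """Noiseless thermogram from the pure-DOPC calorimetry preset."""
    tg, truth = synth.gen_thermogram(synth.dsc_preset("dopc_1to0"))
    return tg, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
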