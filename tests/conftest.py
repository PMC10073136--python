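import numpy as np
import pytest

from nqrauth import (
    BENZOCAINE,
    CoilSpec,
    PulseSpec,
    SLSEParams,
    package_presets,
    simulate_echo_train,
)


@pytest.fixture(scope="session")
def coil():
    """The reference 7 cm, 11-turn planar coil."""
    return CoilSpec()


@pytest.fixture(scope="session")
def pulse():
    return PulseSpec()


@pytest.fixture(scope="session")
def slse_params():
    return SLSEParams()


@pytest.fixture(scope="session")
def thin_paper():
    return package_presets()["thin_paper"]


@pytest.fixture(scope="session")
def presets():
    return package_presets()


@pytest.fixture(scope="session")
def noiseless_train(coil, pulse, slse_params, thin_paper):
    """Benzocaine reference train with no noise."""
    return simulate_echo_train(
        BENZOCAINE, thin_paper, coil, pulse, slse_params, noise_sigma=0.0, seed=1
    )


@pytest.fixture(scope="session")
def sigma_for_snr(noiseless_train, slse_params):
    """Per-scan noise sd giving a target first-echo amplitude SNR after averaging."""
    peak = float(np.abs(noiseless_train.samples).max())

    def _sigma(snr: float) -> float:
        return peak * np.sqrt(slse_params.n_scans) / snr

    return _sigma
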