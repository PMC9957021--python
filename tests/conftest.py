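import numpy as np
import pytest

from tcmbmd import PhantomSpec, make_spectrum, render_phantom


@pytest.fixture(scope="session")
def spectrum_100():
    return make_spectrum(100.0)


@pytest.fixture(scope="session")
def spectrum_120():
    return make_spectrum(120.0)


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def noiseless_phantoms(phantom_spec, spectrum_100, spectrum_120):
    """Noise-free renders at both tube voltages, (volume, labels) per kVp."""
    return {
        100: render_phantom(phantom_spec, spectrum_100, noise_sd_hu=0.0),
        120: render_phantom(phantom_spec, spectrum_120, noise_sd_hu=0.0),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20230213)
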