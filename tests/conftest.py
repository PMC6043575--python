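import numpy as np
import pytest

from garcinia_auth.spectra import (SpectrumSimConfig, build_signature_library,
                                   simulate_spectrum)


@pytest.fixture(scope="session")
def signatures():
    return build_signature_library()


@pytest.fixture(scope="session")
def clean_spectrum(signatures):
    """Noise-free spectrum with 1 mg each of HCA and lactone in 10 mg."""
    cfg = SpectrumSimConfig(
        concentrations={"hca": 1.0, "hca_lactone": 1.0},
        noise_sd=0.0, sugar_background=False, seed=0)
    return simulate_spectrum(cfg, signatures)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
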