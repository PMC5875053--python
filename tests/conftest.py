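import numpy as np
import pytest

from qrsdet import SyntheticSpec, generate_synthetic


@pytest.fixture(scope="session")
def clean_spec():
    """A noise-free, jitter-free 60 s record at 72 bpm."""
    return SyntheticSpec(duration_s=60, fs=360, heart_rate_bpm=72,
                         rr_jitter_frac=0.0, drift_amp=0.0,
                         powerline_amp=0.0, noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def clean_record(clean_spec):
    return generate_synthetic(clean_spec)


@pytest.fixture(scope="session")
def noisy_record():
    """Default noise conditions: drift, powerline, white noise, RR jitter."""
    return generate_synthetic(SyntheticSpec(duration_s=60, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
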