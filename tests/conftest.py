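import numpy as np
import pytest

from ecgcrypt.synthetic import NoiseSpec, SyntheticECGConfig, generate_ecg

NO_NOISE = dict(
    baseline_amplitude=0.0, powerline_amplitude=0.0, white_sd=0.0
)


@pytest.fixture
def clean_ecg():
    """Noise-free, jitter-free 20 s ECG at 500 Hz, hr 60: 20 beats 1 s apart."""
    cfg = SyntheticECGConfig(
        hr_mean=60.0, hr_sd=0.0, noise=NoiseSpec(**NO_NOISE), seed=7
    )
    return generate_ecg(cfg)


@pytest.fixture
def default_ecg():
    """Default 10,000-sample fixture with mild realistic noise."""
    return generate_ecg(SyntheticECGConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
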