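import numpy as np
import pytest

from sostim.synth import SynthParams, generate_record


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free 0.8 Hz slow-oscillation train, 60 s at 250 Hz."""
    params = SynthParams(duration_s=60, fs=250, so_freq=0.8, so_amp=100.0,
                         so_freq_jitter=0.0, noise_rms=0.0, seed=1)
    return generate_record(params)


@pytest.fixture(scope="session")
def noisy_record():
    """Realistic deep-sleep segment: SO train plus 15 uV 1/f noise."""
    params = SynthParams(duration_s=120, fs=250, noise_rms=15.0, seed=7)
    return generate_record(params)


@pytest.fixture(scope="session")
def clean_tone_100hz():
    """Clean 0.8 Hz train at the PLL tuning rate (Fs = 100 Hz)."""
    params = SynthParams(duration_s=60, fs=100, so_freq=0.8, so_amp=100.0,
                         so_freq_jitter=0.0, noise_rms=0.0, seed=5)
    return generate_record(params)
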