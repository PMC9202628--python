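import numpy as np
import pytest

from aquaforecast.synthetic import ToneSpec, gen_multitone
from aquaforecast.timeseries import UniformSeries


@pytest.fixture(scope="session")
def two_tone():
    """Noiseless equal-amplitude tones at 0.02 and 0.2 cycles/sample, n=512."""
    noisy, clean = gen_multitone([ToneSpec(0.02), ToneSpec(0.2)], 512, 0.0)
    t = np.arange(512.0)
    components = np.array([np.sin(2 * np.pi * 0.02 * t), np.sin(2 * np.pi * 0.2 * t)])
    return clean, components


@pytest.fixture(scope="session")
def trend_tone_fixture():
    """Clean trend + two tones, n=1024 (basis of the denoising fixture)."""
    n = 1024
    t = np.arange(float(n))
    clean = 0.002 * t + np.sin(2 * np.pi * 0.02 * t) + 0.6 * np.sin(2 * np.pi * 0.15 * t)
    return clean


def make_noisy_trend_tone(clean: np.ndarray, seed: int, noise_sd: float = 0.2) -> UniformSeries:
    rng = np.random.default_rng(seed)
    return UniformSeries("fixture", clean + noise_sd * rng.standard_normal(clean.size))
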