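import numpy as np
import pytest

from tightrope.synthdata import SimulationConfig, Species


@pytest.fixture
def noiseless_config():
    """One static molecule, no camera noise: argmax equals truth exactly."""
    return SimulationConfig(
        species=[Species(composition=("A",), count=1)],
        background_mean=0.0, read_noise_sigma=0.0, shot_noise=False)


@pytest.fixture
def snr10_config():
    """Amplitude ~10x the background SD (sqrt(100 + 2^2) ~ 10.2)."""
    return SimulationConfig(
        species=[Species(composition=("A",), count=3, amplitude=105.0)],
        min_separation_um=2.5, background_mean=100.0, read_noise_sigma=2.0)


def render_spot(shape, x, y, amplitude=100.0, sigma=1.3, background=0.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return background + amplitude * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
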