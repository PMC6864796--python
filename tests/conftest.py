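import numpy as np
import pytest

from gaitfes import DetectorConfig, GaitSimConfig, process_stream, simulate_gait


@pytest.fixture(scope="session")
def clean_sim():
    """A noiseless 10-cycle recording at 1.2 s/cycle with ground truth."""
    cfg = GaitSimConfig(
        n_cycles=10, cycle_duration=1.2, noise_sd_acc=0.0, noise_sd_gyr=0.0, seed=7
    )
    return simulate_gait(cfg)


@pytest.fixture(scope="session")
def clean_detection(clean_sim):
    stream, truth = clean_sim
    return process_stream(stream, DetectorConfig()), truth


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-noise recording (sensor-realistic sd) with ground truth."""
    cfg = GaitSimConfig(n_cycles=10, cycle_duration=1.2, seed=11)
    return simulate_gait(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
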