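import numpy as np
import pytest

from nystagdet import FrameSpec, GeneratorConfig, make_training_days, train_from_days

FS = 41.5


@pytest.fixture(scope="session")
def default_spec():
    return FrameSpec()


@pytest.fixture(scope="session")
def small_model():
    """Ensemble trained on a small synthetic set at default noise."""
    days = make_training_days(12, 12, day_length=300.0, seed=4242)
    return train_from_days(days, seed=4242)


@pytest.fixture(scope="session")
def noisefree_config():
    """Generator settings with the sensor-noise source switched off
    (background eye movement - drift and saccades - still present)."""
    return GeneratorConfig(noise_sigma=0.0)


@pytest.fixture(scope="session")
def quiet_config():
    """Generator settings with every background source off: the signal is
    exactly the scheduled events."""
    return GeneratorConfig(noise_sigma=0.0, drift_sigma=0.0, saccade_rate=0.0)
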