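import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from harloc import synthio
from harloc.pipeline import PipelineConfig, extract_features

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def locomotion_recording():
    """Default 4-class synthetic session (480 s, 10 Hz, noise_sd 0.1)."""
    spec = synthio.default_locomotion_scenario(seed=7)
    rec, truth = synthio.generate_recording(spec)
    return rec, truth


@pytest.fixture(scope="session")
def locomotion_features(locomotion_recording):
    """Locomotion feature matrix for the default scenario (126 x 54)."""
    rec, _ = locomotion_recording
    return extract_features(PipelineConfig(seed=7), rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
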