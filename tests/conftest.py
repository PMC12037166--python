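import numpy as np
import pytest

from reactivate.features import epoch_blocks
from reactivate.preprocess import preprocess_session
from reactivate.synthetic import SimConfig, simulate_subject


@pytest.fixture(scope="session")
def small_config():
    """Reduced-ROI configuration for fast unit tests (full-length runs)."""
    return SimConfig(n_voxels=30)


@pytest.fixture(scope="session")
def small_subject(small_config):
    return simulate_subject(small_config, "sub-01", 42)


@pytest.fixture(scope="session")
def training_samples(small_subject):
    """Labeled block samples from the first three task sessions."""
    samples = []
    for series, events in small_subject.task_sessions[:3]:
        samples += epoch_blocks(preprocess_session(series), events)
    return samples


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
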