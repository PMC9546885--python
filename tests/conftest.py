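import numpy as np
import pytest

from eegaec.core import DEFAULT_BANDS
from eegaec.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def beta1():
    return DEFAULT_BANDS[2]


@pytest.fixture(scope="session")
def mini_cohort():
    """Tiny but complete synthetic cohort for structural/pipeline tests."""
    cfg = SimulationConfig(
        n_per_group=3, fs=256.0, duration=20.0, n_sensors=8, seed=11
    )
    return simulate_cohort(cfg)
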