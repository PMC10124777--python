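import numpy as np
import pytest

from gazemark.config import Screen, SimulationConfig
from gazemark.pipeline import run_in_memory
from gazemark.rois import build_battery_spec
from gazemark.simulate import simulate_cohort


@pytest.fixture(scope="session")
def micro_config() -> SimulationConfig:
    return SimulationConfig(
        n_asd=8, n_td=6, sample_rate_hz=20, plr_sample_rate_hz=100, seed=7
    )


@pytest.fixture(scope="session")
def micro_cohort(micro_config):
    return simulate_cohort(micro_config)


@pytest.fixture(scope="session")
def micro_bundle(micro_config):
    return run_in_memory(micro_config, keep_samples=True)


@pytest.fixture(scope="session")
def battery(micro_config):
    return build_battery_spec(micro_config, np.random.default_rng(0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def screen() -> Screen:
    return Screen()
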