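import numpy as np
import pytest

from methanobatch import NoiseModel, generate_observations, table1_scenarios

NOISE_FREE = NoiseModel(pressure_sigma=0.0, cell_sigma_log10=0.0, seed=0)


@pytest.fixture(scope="session")
def presets():
    return table1_scenarios()


@pytest.fixture(scope="session")
def series_1_1(presets):
    return presets["series_1_1"]


@pytest.fixture(scope="session")
def series_2_1(presets):
    return presets["series_2_1"]


@pytest.fixture(scope="session")
def clean_obs_1_1(series_1_1):
    """Noise-free series-1.1 observations with the default 3 cell counts."""
    return generate_observations(series_1_1, noise=NOISE_FREE)


@pytest.fixture(scope="session")
def clean_obs_2_1(series_2_1):
    return generate_observations(series_2_1, noise=NOISE_FREE)
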