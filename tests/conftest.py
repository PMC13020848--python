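"""Shared fixtures: small seeded synthetic datasets and environments."""

import numpy as np
import pytest

from ghctl.oracle import OracleParams, make_dataset
from ghctl.weather import WeatherGenConfig, generate_weather


@pytest.fixture(scope="session")
def weather_week():
    """One seeded week of synthetic weather (2016 records)."""
    return generate_weather(WeatherGenConfig(n_days=7, seed=123))


@pytest.fixture(scope="session")
def quiet_params():
    """Oracle parameters with all observation noise disabled."""
    return OracleParams().no_noise()


@pytest.fixture(scope="session")
def small_dataset():
    """A 6-week linked synthetic dataset (shared, read-only)."""
    return make_dataset(weeks=6, seed=77)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
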