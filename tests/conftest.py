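import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `reference`

from phenoflex import (ChillSubmodelParams, HeatSubmodelParams,
                       WeatherGenConfig, generate_weather,
                       seasons_from_weather)


@pytest.fixture(scope="session")
def default_chill():
    return ChillSubmodelParams()


@pytest.fixture(scope="session")
def default_heat():
    return HeatSubmodelParams()


@pytest.fixture(scope="session")
def weather_5yr():
    """Five years of synthetic mid-latitude daily weather."""
    return generate_weather(WeatherGenConfig(first_year=2000, years=5, seed=42))


@pytest.fixture(scope="session")
def seasons_5yr(weather_5yr):
    return seasons_from_weather(weather_5yr, latitude=40.0)


@pytest.fixture(scope="session")
def one_season(seasons_5yr):
    return seasons_5yr[2002]


def random_winter_temps(rng: np.random.Generator, n_hours: int) -> np.ndarray:
    """Plausible winter-to-spring hourly series for oracle comparisons."""
    base = np.linspace(12.0, 16.0, n_hours)
    seasonal = -10.0 * np.sin(np.linspace(0, np.pi, n_hours))
    diurnal = 5.0 * np.sin(2 * np.pi * np.arange(n_hours) / 24.0)
    noise = rng.normal(0, 2.0, n_hours)
    return base + seasonal + diurnal + noise
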