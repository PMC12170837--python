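import numpy as np
import pytest

from heatosa.synthetic import (
    CohortConfig,
    WeatherConfig,
    simulate_cohort,
    simulate_country_weather,
)


@pytest.fixture(scope="session")
def weather():
    """Three years of daily weather for a temperate mid-latitude country."""
    return simulate_country_weather(
        WeatherConfig(start_year=2021, end_year=2023, seed=11)
    )


@pytest.fixture(scope="session")
def calibrated_config(weather):
    """Cohort config whose cumulative RR(27.3 vs 6.4 degC) is exactly 1.45
    (1.49 for the severe outcome)."""
    return CohortConfig.calibrated(
        weather, rr=1.45, rr_severe=1.49, n_users=120, nights_per_user=365, seed=5
    )


@pytest.fixture(scope="session")
def panel(weather, calibrated_config):
    return simulate_cohort(weather, calibrated_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)
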