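import numpy as np
import pandas as pd
import pytest

from heatmorb import synthetic_data as sd
from heatmorb import thermophysiology as tp
from heatmorb.exposure import build_exposure


def constant_weather(temp_c, rh_pct, days=3, start="2019-07-01", freq="h"):
    ts = pd.date_range(start, periods=days * 24, freq=freq)
    return pd.DataFrame(
        {"timestamp": ts, "temp_c": float(temp_c), "rh_pct": float(rh_pct)}
    )


@pytest.fixture(scope="session")
def hot_scenario():
    return sd.WeatherScenario.hot_summer(n_years=7, seed=3)


@pytest.fixture(scope="session")
def hot_weather(hot_scenario):
    return sd.generate_weather(hot_scenario)


@pytest.fixture(scope="session")
def hot_thermo(hot_weather):
    return tp.simulate_season(hot_weather)


@pytest.fixture(scope="session")
def hot_exposure(hot_weather, hot_thermo):
    return build_exposure(hot_weather, hot_thermo)


@pytest.fixture(scope="session")
def age_pyramid():
    return sd.generate_age_composition(3.0)
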