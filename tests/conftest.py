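import datetime as dt

import pytest

from weedcomp import ModelConstants, SimulationConfig, WeatherDay, WeatherSeries
from weedcomp.synthetic import (
    cultivar_fixtures,
    generate_weather,
    preset_climatologies,
)


@pytest.fixture(scope="session")
def traits():
    return cultivar_fixtures()


@pytest.fixture(scope="session")
def consort(traits):
    return traits["Consort"]


@pytest.fixture(scope="session")
def duxford(traits):
    return traits["Duxford"]


@pytest.fixture(scope="session")
def santiago(traits):
    return traits["KWS Santiago"]


@pytest.fixture(scope="session")
def blackgrass(traits):
    return traits["blackgrass"]


@pytest.fixture(scope="session")
def constants():
    return ModelConstants()


def make_constant_weather(n_days=400, tmean=16.0, radiation=14.0, rain=3.0,
                          start=dt.date(2020, 3, 1), latitude=51.8, half_range=4.0):
    days = [
        WeatherDay(start + dt.timedelta(days=i), tmean - half_range,
                   tmean + half_range, radiation, rain)
        for i in range(n_days)
    ]
    return WeatherSeries(days, latitude)


@pytest.fixture(scope="session")
def warm_weather():
    """Constant warm, bright, moist weather: a compressed synthetic season."""
    return make_constant_weather()


@pytest.fixture(scope="session")
def autumn_weather():
    """One seeded synthetic UK-type season starting 1 September."""
    clim = preset_climatologies()["rothamsted_default"]
    return generate_weather(clim, dt.date(2005, 9, 1), 400, seed=1)


@pytest.fixture(scope="session")
def autumn_config(consort, blackgrass):
    return SimulationConfig(
        sowing_date=dt.date(2005, 9, 20),
        crop_traits=consort,
        weed_traits=blackgrass,
        crop_density=250.0,
        weed_density=80.0,
    )
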