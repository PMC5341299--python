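"""Seeded synthetic inputs: weather, trait sets, toy scenarios.

The weather generator emulates a temperate lowland-UK site at ~51.8 °N
(Harpenden-like climatology): a seasonal temperature sinusoid with its
minimum in mid-January plus AR(1) day-to-day noise, a seasonal clear-sky
radiation sinusoid damped by a daily cloudiness draw, and intermittent
rainfall from a two-state (wet/dry) Markov chain with gamma-distributed
wet-day amounts.  It reproduces the statistical structure the analysis
needs — realistic thermal-time accumulation, autumn-to-summer radiation
contrast, year-to-year variability from independent seeds — without being
fitted to any observed record.

Also provided: trait sets for the three winter-wheat cultivars (Consort,
Duxford, KWS Santiago) and a default black-grass (*Alopecurus
myosuroides*) trait set, plus deterministic micro-scenarios for tests.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, replace

import numpy as np

from .canopy import CultivarTraits
from .physiology import ModelConstants
from .simulation import SimulationConfig
from .weather import WeatherDay, WeatherSeries

__all__ = [
    "Climatology",
    "generate_weather",
    "preset_climatologies",
    "cultivar_fixtures",
    "toy_scenarios",
]


@dataclass(frozen=True)
class Climatology:
    """Parameters of the stochastic weather generator.

    Temperature: annual mean (°C), seasonal half-amplitude (°C), AR(1)
    autocorrelation and innovation sd of the daily anomaly, and the diurnal
    half-range (tmax − tmean).  Radiation: clear-sky seasonal sinusoid
    (mean and half-amplitude, MJ m⁻² d⁻¹) multiplied by a daily cloudiness
    factor 0.35 + 0.65·u, u ~ U(0,1), clipped at ≥ 0.5 MJ.  Rain: wet/dry
    Markov chain (p(wet|wet), p(wet|dry)) with gamma wet-day amounts of the
    given shape and mean (mm).
    """

    annual_mean_temp: float = 9.8
    seasonal_amplitude: float = 6.5
    ar1_rho: float = 0.7
    temp_noise_sd: float = 2.0
    diurnal_half_range: float = 4.0
    radiation_mean: float = 13.0
    radiation_amplitude: float = 11.0
    p_wet_wet: float = 0.6
    p_wet_dry: float = 0.3
    rain_gamma_shape: float = 0.8
    rain_mean_mm: float = 4.0
    latitude: float = 51.8

    def __post_init__(self) -> None:
        for p in (self.p_wet_wet, self.p_wet_dry):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rain transition probabilities must be in [0, 1]")
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|ar1_rho| must be < 1")
        if self.temp_noise_sd < 0 or self.diurnal_half_range < 0:
            raise ValueError("temperature spreads must be non-negative")


#: Day of year of the coldest (and dimmest) point of the seasonal cycle.
_COLDEST_DOY = 15  # mid-January


def generate_weather(
    climatology: Climatology,
    start_date: _dt.date,
    n_days: int,
    seed: int,
) -> WeatherSeries:
    """Generate ``n_days`` of daily weather, fully reproducible from ``seed``."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    c = climatology
    rng = np.random.default_rng(seed)
    doy = np.array([
        (start_date + _dt.timedelta(days=i)).timetuple().tm_yday for i in range(n_days)
    ])
    phase = 2.0 * math.pi * (doy - _COLDEST_DOY) / 365.25
    base_temp = c.annual_mean_temp - c.seasonal_amplitude * np.cos(phase)
    # AR(1) anomaly with stationary variance temp_noise_sd²
    innov_sd = c.temp_noise_sd * math.sqrt(1.0 - c.ar1_rho**2)
    anomaly = np.empty(n_days)
    anomaly[0] = rng.normal(0.0, c.temp_noise_sd) if c.temp_noise_sd > 0 else 0.0
    z = rng.normal(0.0, 1.0, size=n_days)
    for i in range(1, n_days):
        anomaly[i] = c.ar1_rho * anomaly[i - 1] + innov_sd * z[i]
    tmean = base_temp + anomaly

    clear_sky = np.maximum(0.0, c.radiation_mean - c.radiation_amplitude * np.cos(phase))
    cloud = 0.35 + 0.65 * rng.uniform(size=n_days)
    radiation = np.maximum(0.5, clear_sky * cloud)

    wet = np.zeros(n_days, dtype=bool)
    u = rng.uniform(size=n_days)
    wet[0] = u[0] < c.p_wet_dry
    for i in range(1, n_days):
        p = c.p_wet_wet if wet[i - 1] else c.p_wet_dry
        wet[i] = u[i] < p
    amounts = rng.gamma(c.rain_gamma_shape, c.rain_mean_mm / c.rain_gamma_shape, size=n_days)
    rain = np.where(wet, amounts, 0.0)

    days = [
        WeatherDay(
            date=start_date + _dt.timedelta(days=i),
            tmin=float(tmean[i] - c.diurnal_half_range),
            tmax=float(tmean[i] + c.diurnal_half_range),
            radiation=float(radiation[i]),
            rain=float(rain[i]),
        )
        for i in range(n_days)
    ]
    return WeatherSeries(days, latitude=c.latitude)


def preset_climatologies() -> dict[str, Climatology]:
    """Named climatologies: the default site plus cold and warm years.

    The cold and warm presets shift the annual mean by ∓1.5 °C, spanning
    the kind of between-season contrast over which weed competitive
    performance is known to swing.
    """
    default = Climatology()
    return {
        "rothamsted_default": default,
        "cold_year": replace(default, annual_mean_temp=default.annual_mean_temp - 1.5),
        "warm_year": replace(default, annual_mean_temp=default.annual_mean_temp + 1.5),
    }


def cultivar_fixtures() -> dict[str, CultivarTraits]:
    """Trait sets for the three wheat cultivars and the default weed.

    The wheat values are the published parameter sets for Consort (the
    original winter-wheat parameterisation), Duxford (a strongly
    weed-suppressive cultivar: fast leaf appearance, high specific leaf
    area, vigorous early area growth) and KWS Santiago (weakly
    suppressive: slower early growth, delayed stem extension).  The
    black-grass set is a documented stand-in with the qualitative features
    of the species — faster relative area growth than any of the wheats,
    small initial seedling area, high specific leaf area, late height
    inflexion — not a published parameterisation.
    """
    return {
        "Consort": CultivarTraits(
            name="Consort", rwr=0.71, ssa=0.003, phyllochron=90.0, sla=0.019,
            rgr_ga=0.0089, l0=0.64, height_a=7.4, height_c=77.9,
            height_b=0.0085, height_m=624.0, k_ext=0.60,
        ),
        "Duxford": CultivarTraits(
            name="Duxford", rwr=0.705, ssa=0.00545, phyllochron=67.5, sla=0.0385,
            rgr_ga=0.0116, l0=0.674, height_a=1.36, height_c=81.845,
            height_b=0.004218, height_m=685.0, k_ext=0.60,
        ),
        "KWS Santiago": CultivarTraits(
            name="KWS Santiago", rwr=0.681, ssa=0.00504, phyllochron=69.5, sla=0.0346,
            rgr_ga=0.0096, l0=0.715, height_a=5.73, height_c=77.299,
            height_b=0.005559, height_m=822.6, k_ext=0.60,
        ),
        "blackgrass": CultivarTraits(
            name="blackgrass", rwr=0.60, ssa=0.004, phyllochron=95.0, sla=0.045,
            rgr_ga=0.013, l0=1.2, height_a=4.0, height_c=80.0,
            height_b=0.006, height_m=700.0, k_ext=0.50,
            # autumn-germinating black-grass runs a warmer base temperature
            # than wheat; it establishes vigorously (l0 covers seedling
            # size plus early tillering), overwinters as a rosette that
            # holds its place in the lower canopy, and as a long-day plant
            # heads in early May and stays green into mid-July when seed
            # is shed, regardless of sowing date
            t_base=2.0, anthesis_daylength=14.5, senescence_dd=650.0,
        ),
    }


def _constant_weather(
    start: _dt.date, n_days: int, tmean: float, radiation: float, rain: float,
    latitude: float = 51.8, half_range: float = 4.0,
) -> WeatherSeries:
    days = [
        WeatherDay(start + _dt.timedelta(days=i), tmean - half_range,
                   tmean + half_range, radiation, rain)
        for i in range(n_days)
    ]
    return WeatherSeries(days, latitude)


def toy_scenarios() -> dict[str, tuple[SimulationConfig, WeatherSeries]]:
    """Deterministic micro-scenarios for tests and quick inspection.

    * ``constant_short`` — warm constant weather so the whole season
      compresses into a few months.
    * ``symmetric_duel`` — crop and weed share one trait set, density and
      emergence lag; competition must end in a dead heat.
    * ``weed_free`` — no weed; yield loss must be exactly zero.
    * ``drought`` / ``rainfed`` — identical but for rainfall after
      emergence; the drought twin must yield less.
    """
    fixtures = cultivar_fixtures()
    wheat = fixtures["Consort"]
    weed = fixtures["blackgrass"]
    start = _dt.date(2020, 3, 1)
    constants = ModelConstants()

    warm = _constant_weather(start, 400, tmean=16.0, radiation=14.0, rain=3.0)
    scenarios: dict[str, tuple[SimulationConfig, WeatherSeries]] = {}
    scenarios["constant_short"] = (
        SimulationConfig(sowing_date=start, crop_traits=wheat, weed_traits=weed,
                         crop_density=250.0, weed_density=80.0, constants=constants),
        warm,
    )
    scenarios["symmetric_duel"] = (
        SimulationConfig(sowing_date=start, crop_traits=wheat, weed_traits=wheat,
                         crop_density=150.0, weed_density=150.0,
                         crop_emergence_lag=8, weed_emergence_lag=8,
                         constants=constants),
        warm,
    )
    scenarios["weed_free"] = (
        SimulationConfig(sowing_date=start, crop_traits=wheat, weed_traits=weed,
                         crop_density=250.0, weed_density=0.0, constants=constants),
        warm,
    )
    dry = _constant_weather(start, 400, tmean=16.0, radiation=14.0, rain=0.0)
    scenarios["drought"] = (
        SimulationConfig(sowing_date=start, crop_traits=wheat, weed_traits=weed,
                         crop_density=250.0, weed_density=80.0, constants=constants),
        dry,
    )
    scenarios["rainfed"] = scenarios["constant_short"]
    return scenarios
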