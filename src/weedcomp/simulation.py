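"""One crop–weed season: configuration, the daily loop, and outcomes.

A season starts at sowing and ends at crop maturity.  Each day the model

1. advances each emerged species' biological clocks,
2. grows green area — exponentially on the effective-day-degree clock
   while the canopy is open (sink-limited), or from light capture once the
   combined green area index has latched past the closure threshold
   (source-limited): stratify the canopy by height, attenuate PAR through
   the layers by Beer's law, convert each species' absorbed PAR to dry
   matter, and allocate it to root/leaf/stem/grain pools,
3. steps the shared soil-water bucket and applies its stress factor, and
4. after anthesis, fills grain by new assimilate plus relocation from
   leaf+stem while green area senesces.

Every weedy run is paired with a weed-free run on the same weather, from
which percentage yield loss is computed.  Weed seed return is proportional
to weed shoot biomass at harvest.

Before canopy closure the two species do not interact at all: the weed's
trajectory is bit-identical with and without the crop present.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .canopy import (
    CultivarTraits,
    PlantStand,
    build_layers,
    partition_light,
    sink_limited_gai,
    height_at,
)
from .phenology import DevStage, PhenoClock, advance_clock, emergence_day
from .physiology import (
    ModelConstants,
    SoilWater,
    daily_assimilation,
    marginal_area_per_dm,
    partition_biomass,
    senescence_grainfill_step,
    temperature_factor,
    water_balance_step,
)
from .weather import WeatherSeries, photoperiod, thermal_time_increment

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "SeasonError",
    "run_season",
    "yield_loss",
    "seed_return",
    "load_config",
]

#: Fraction of global radiation that is photosynthetically active.
PAR_FRACTION = 0.5

CROP = "crop"
WEED = "weed"


class SeasonError(RuntimeError):
    """Raised when a season cannot be completed (e.g. weather runs out)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Inputs for one season run."""

    sowing_date: _dt.date
    crop_traits: CultivarTraits
    weed_traits: CultivarTraits
    crop_density: float = 250.0
    weed_density: float = 80.0
    crop_emergence_lag: int = 10
    weed_emergence_lag: int = 7
    constants: ModelConstants = field(default_factory=ModelConstants)
    latitude: float = 51.8

    def __post_init__(self) -> None:
        if self.crop_density < 0 or self.weed_density < 0:
            raise ValueError("densities must be non-negative")
        if self.crop_emergence_lag < 0 or self.weed_emergence_lag < 0:
            raise ValueError("emergence lags must be non-negative")


@dataclass(frozen=True)
class SimulationResult:
    """Season outcomes of a weedy run and its paired weed-free run."""

    grain_yield: float  # t ha⁻¹, weedy run
    weedfree_yield: float  # t ha⁻¹
    yield_loss: float  # %
    weed_shoot_biomass: float  # g m⁻², above-ground at harvest
    weed_seed_return: float  # seeds m⁻²
    sowing_date: _dt.date
    harvest_date: _dt.date
    season_mean_temp: float  # °C, sowing → harvest
    accumulated_tt: float  # dd, crop emergence → maturity
    trajectory: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        return {
            "grain_yield_t_ha": self.grain_yield,
            "weedfree_yield_t_ha": self.weedfree_yield,
            "yield_loss_pct": self.yield_loss,
            "weed_shoot_biomass_g_m2": self.weed_shoot_biomass,
            "weed_seed_return_m2": self.weed_seed_return,
            "sowing_date": self.sowing_date.isoformat(),
            "harvest_date": self.harvest_date.isoformat(),
            "season_mean_temp_c": self.season_mean_temp,
            "accumulated_tt_dd": self.accumulated_tt,
        }


class _Species:
    """Mutable per-species season state (internal)."""

    __slots__ = (
        "name", "traits", "density", "stand", "clock", "stage",
        "emergence", "anthesis_shoot", "anthesis_gai", "grain_bearing",
        "fill_span",
    )

    def __init__(self, name: str, traits: CultivarTraits, density: float,
                 emergence: _dt.date, grain_bearing: bool) -> None:
        self.name = name
        self.traits = traits
        self.density = density
        self.stand = PlantStand(species=name, traits=traits, density=density)
        self.clock = PhenoClock()
        self.stage = DevStage.PRE_EMERGENCE
        self.emergence = emergence
        self.anthesis_shoot = 0.0
        self.anthesis_gai = 0.0
        self.grain_bearing = grain_bearing
        self.fill_span = 0.0  # set once constants are known


def _sink_phase_pools(sp: _Species) -> None:
    """Derive biomass pools from green area during the sink-limited phase.

    Early growth is area-driven by definition; mass follows area through
    the specific leaf area, with roots added at the trait root weight
    ratio.  Shoot mass is treated as all leaf this early in the season.
    """
    leaf = sp.stand.green_area_index / sp.traits.sla
    sp.stand.leaf = leaf
    sp.stand.stem = 0.0
    sp.stand.root = leaf * sp.traits.rwr / (1.0 - sp.traits.rwr)


def _run_one(
    config: SimulationConfig,
    weather: WeatherSeries,
    include_weed: bool,
    collect_trajectory: bool,
) -> dict:
    consts = config.constants
    species: list[_Species] = [
        _Species(CROP, config.crop_traits,
                 config.crop_density,
                 emergence_day(config.sowing_date, config.crop_emergence_lag),
                 grain_bearing=True),
    ]
    if include_weed and config.weed_density > 0:
        species.append(
            _Species(WEED, config.weed_traits, config.weed_density,
                     emergence_day(config.sowing_date, config.weed_emergence_lag),
                     grain_bearing=False)
        )
    crop = species[0]
    for sp in species:
        sp.fill_span = (sp.traits.senescence_dd
                        if sp.traits.senescence_dd is not None
                        else consts.grain_fill_dd)
    k_ext = {s.name: s.traits.k_ext for s in species}

    if config.sowing_date not in weather:
        raise SeasonError(
            f"weather series [{weather.start}..{weather.end}] does not cover sowing "
            f"date {config.sowing_date}"
        )

    soil = SoilWater(stored=consts.soil_capacity, capacity=consts.soil_capacity,
                     wilting=consts.wilting_point)
    switched = False
    temps: list[float] = []
    rows: list[dict] = [] if collect_trajectory else None

    date = config.sowing_date
    harvest: Optional[_dt.date] = None
    while True:
        if date not in weather:
            raise SeasonError(f"weather exhausted at {date} before crop maturity")
        day = weather.day(date)
        temps.append(day.tmean)
        daylength = photoperiod(date.timetuple().tm_yday, config.latitude)

        # 1. clocks & stage bookkeeping
        edd_prev = {sp.name: sp.clock.edd for sp in species}
        for sp in species:
            if sp.stage == DevStage.PRE_EMERGENCE:
                if date >= sp.emergence:
                    sp.stage = DevStage.VEGETATIVE
                    sp.stand.green_area_index = sink_limited_gai(sp.traits, sp.density, 0.0)
                    _sink_phase_pools(sp)
                    sp.stand.height = height_at(0.0, sp.traits)
                else:
                    continue
            else:
                sp.clock = advance_clock(
                    sp.clock, day, sp.traits, config.latitude, consts.r_ref,
                    anthesis_reached=sp.stage >= DevStage.REPRODUCTIVE,
                )
            sp.stand.clock = sp.clock
            sp.stand.height = height_at(sp.clock.ptt, sp.traits)
            fln = sp.traits.final_leaf_number or consts.final_leaf_number
            if sp.stage == DevStage.VEGETATIVE:
                long_day = (
                    sp.traits.anthesis_daylength is not None
                    and daylength >= sp.traits.anthesis_daylength
                    and date.timetuple().tm_yday <= 172  # daylength still increasing
                )
                if sp.clock.leaf_number(sp.traits) >= fln or long_day:
                    sp.stage = DevStage.REPRODUCTIVE
                    sp.anthesis_shoot = sp.stand.leaf + sp.stand.stem
                    sp.anthesis_gai = sp.stand.green_area_index
            elif (sp.stage == DevStage.REPRODUCTIVE
                    and sp.clock.tt_post_anthesis >= sp.fill_span):
                sp.stage = DevStage.MATURE
                sp.stand.green_area_index = 0.0
            sp.stand.stage = sp.stage

        emerged = [sp for sp in species if sp.stage > DevStage.PRE_EMERGENCE]
        dd_today = thermal_time_increment(day.tmin, day.tmax, config.crop_traits.t_base)

        # 2. shared soil-water bucket, once per day in either phase.  Total
        # withdrawal equals PET regardless of canopy, so the store (and the
        # stress factor) is identical with and without the weed present.
        total_gai = sum(sp.stand.green_area_index for sp in emerged)
        soil, water_factor = water_balance_step(soil, day, total_gai, consts)
        tfac = temperature_factor(day.tmean, 0.0, consts.t_ref_growth)
        i0 = day.radiation * PAR_FRACTION

        # 3. growth
        dm: dict[str, float] = {s.name: 0.0 for s in species}
        if not switched:
            # open canopy: the species are fully independent.  Each grows by
            # the lesser of its sink-limited area demand (the exponential on
            # its effective-day-degree clock) and the light supply through
            # its own single-species canopy.
            supply: dict[str, float] = {}
            own_absorbed: dict[str, float] = {}
            for sp in emerged:
                if sp.stage == DevStage.MATURE:
                    continue
                own_layers = build_layers([sp.stand])
                own = partition_light(own_layers, i0, k_ext)
                par_area = [
                    (par, layer.area.get(sp.name, 0.0))
                    for par, layer in zip(own.absorbed_by_layer.get(sp.name, ()), own_layers)
                ]
                supply[sp.name] = daily_assimilation(
                    par_area, daylength, consts, water_factor, tfac
                )
                own_absorbed[sp.name] = own.absorbed.get(sp.name, 0.0)
            proposed: dict[str, float] = {}
            for sp in emerged:
                if sp.stage != DevStage.VEGETATIVE:
                    continue
                d_edd = sp.clock.edd - edd_prev[sp.name]
                dgai_demand = sp.stand.green_area_index * math.expm1(
                    sp.traits.rgr_ga * d_edd
                )
                m = marginal_area_per_dm(
                    sp.clock.leaf_number(sp.traits), sp.traits, consts
                )
                proposed[sp.name] = (
                    min(dgai_demand / m, supply[sp.name]) if m > 0 else 0.0
                )
            for sp in emerged:
                if sp.stage == DevStage.VEGETATIVE:
                    dm[sp.name] = proposed.get(sp.name, 0.0)
                    partition_biomass(dm[sp.name], sp.stand, sp.traits, consts,
                                      is_reproductive=False, update_gai=True)
                elif sp.stage == DevStage.REPRODUCTIVE:
                    # anthesis before canopy closure: assimilate through the
                    # species' own canopy while relocation and senescence run
                    dm[sp.name] = supply[sp.name]
                    partition_biomass(dm[sp.name], sp.stand, sp.traits, consts,
                                      is_reproductive=True,
                                      grain_bearing=sp.grain_bearing,
                                      update_gai=False)
                    senescence_grainfill_step(
                        sp.stand, sp.clock.tt_post_anthesis, dd_today,
                        sp.anthesis_shoot, sp.anthesis_gai, consts,
                        grain_bearing=sp.grain_bearing, fill_dd=sp.fill_span,
                    )
            total_gai = sum(sp.stand.green_area_index for sp in emerged)
            if total_gai >= consts.gai_switch:
                switched = True  # shared-canopy competition from tomorrow on
            absorbed = {s.name: own_absorbed.get(s.name, 0.0) for s in species}
            transmitted = i0 - sum(absorbed.values())
        else:
            layers = build_layers([sp.stand for sp in emerged])
            part = partition_light(layers, i0, k_ext)
            absorbed = {s.name: part.absorbed.get(s.name, 0.0) for s in species}
            transmitted = part.transmitted
            for sp in emerged:
                if sp.stage == DevStage.MATURE:
                    continue
                by_layer = part.absorbed_by_layer.get(sp.name, ())
                par_area = [
                    (par, layer.area.get(sp.name, 0.0))
                    for par, layer in zip(by_layer, layers)
                ]
                dm[sp.name] = daily_assimilation(
                    par_area, daylength, consts, water_factor,
                    temperature_factor(day.tmean, 0.0, consts.t_ref_growth),
                )
                if sp.stage == DevStage.VEGETATIVE:
                    partition_biomass(dm[sp.name], sp.stand, sp.traits, consts,
                                      is_reproductive=False, update_gai=True)
                else:
                    partition_biomass(dm[sp.name], sp.stand, sp.traits, consts,
                                      is_reproductive=True,
                                      grain_bearing=sp.grain_bearing,
                                      update_gai=False)
                    senescence_grainfill_step(
                        sp.stand, sp.clock.tt_post_anthesis, dd_today,
                        sp.anthesis_shoot, sp.anthesis_gai, consts,
                        grain_bearing=sp.grain_bearing, fill_dd=sp.fill_span,
                    )
        if collect_trajectory:
            row = {
                "date": date, "switched": switched, "soil_mm": soil.stored,
                "par_transmitted": transmitted,
            }
            for sp in species:
                row.update({
                    f"{sp.name}_gai": sp.stand.green_area_index,
                    f"{sp.name}_height": sp.stand.height,
                    f"{sp.name}_root": sp.stand.root,
                    f"{sp.name}_leaf": sp.stand.leaf,
                    f"{sp.name}_stem": sp.stand.stem,
                    f"{sp.name}_grain": sp.stand.grain,
                    f"{sp.name}_par_absorbed": absorbed[sp.name],
                    f"{sp.name}_dm": dm[sp.name],
                    f"{sp.name}_stage": int(sp.stage),
                })
            rows.append(row)

        if crop.stage == DevStage.MATURE:
            harvest = date
            break
        date += _dt.timedelta(days=1)

    weed_shoot = 0.0
    for sp in species:
        if sp.name == WEED:
            weed_shoot = sp.stand.above_ground
    return {
        "grain": crop.stand.grain,
        "weed_shoot": weed_shoot,
        "harvest": harvest,
        "mean_temp": sum(temps) / len(temps),
        "tt": crop.clock.tt,
        "trajectory": pd.DataFrame(rows) if collect_trajectory else None,
    }


def run_season(
    config: SimulationConfig,
    weather: WeatherSeries,
    collect_trajectory: bool = False,
) -> SimulationResult:
    """Run one weedy season plus its paired weed-free season.

    Both runs share weather and configuration; the pair differs only in the
    weed being present.  With ``weed_density == 0`` the weedy run *is* the
    weed-free run and the yield loss is exactly zero.  Set
    ``collect_trajectory`` to attach a daily per-species state table (from
    the weedy run) to the result.
    """
    weedy = _run_one(config, weather, include_weed=True,
                     collect_trajectory=collect_trajectory)
    if config.weed_density > 0:
        weedfree = _run_one(config, weather, include_weed=False,
                            collect_trajectory=False)
    else:
        weedfree = weedy
    wf_yield = weedfree["grain"] * 0.01  # g m⁻² → t ha⁻¹
    wd_yield = weedy["grain"] * 0.01
    if wf_yield <= 0:
        raise SeasonError("weed-free grain yield is non-positive; cannot express a loss")
    loss = 0.0 if weedy is weedfree else yield_loss(wd_yield, wf_yield)
    return SimulationResult(
        grain_yield=wd_yield,
        weedfree_yield=wf_yield,
        yield_loss=loss,
        weed_shoot_biomass=weedy["weed_shoot"],
        weed_seed_return=seed_return(weedy["weed_shoot"], config.constants.seeds_per_gram),
        sowing_date=config.sowing_date,
        harvest_date=weedy["harvest"],
        season_mean_temp=weedy["mean_temp"],
        accumulated_tt=weedy["tt"],
        trajectory=weedy["trajectory"],
    )


def yield_loss(weedy: float, weedfree: float) -> float:
    """Percentage yield loss: 100 × (weed-free − weedy) / weed-free."""
    if weedfree <= 0:
        raise ValueError("weed-free yield must be positive")
    return 100.0 * (weedfree - weedy) / weedfree


def seed_return(weed_biomass: float, seeds_per_gram: float = 150.0) -> float:
    """Weed seeds m⁻² produced from shoot biomass (linear)."""
    if weed_biomass < 0:
        raise ValueError("weed biomass must be non-negative")
    return seeds_per_gram * weed_biomass


_TRAIT_KEYS = ["rwr", "ssa", "phyllochron", "sla", "rgr_ga", "l0",
               "height_a", "height_c", "height_b", "height_m", "k_ext"]


_TRAIT_OPTIONAL = ["t_base", "final_leaf_number", "anthesis_daylength", "senescence_dd"]


def _traits_from_table(name: str, table: dict) -> CultivarTraits:
    kwargs = {k: table[k] for k in _TRAIT_KEYS + _TRAIT_OPTIONAL if k in table}
    return CultivarTraits(name=table.get("name", name), **kwargs)


def load_config(path: Union[str, Path]) -> SimulationConfig:
    """Read a run configuration from TOML.

    Expected tables: ``[run]`` (sowing_date, crop_density, weed_density,
    optional emergence lags and latitude), ``[crop]`` / ``[weed]`` trait
    tables keyed rwr, ssa, phyllochron, sla, rgr_ga, l0, height_a,
    height_c, height_b, height_m, k_ext, and an optional ``[constants]``
    table overriding any :class:`~weedcomp.physiology.ModelConstants`
    field.
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    run = doc["run"]
    sowing = run["sowing_date"]
    if not isinstance(sowing, _dt.date):
        sowing = _dt.date.fromisoformat(str(sowing))
    constants = ModelConstants(**doc.get("constants", {}))
    return SimulationConfig(
        sowing_date=sowing,
        crop_traits=_traits_from_table("crop", doc["crop"]),
        weed_traits=_traits_from_table("weed", doc["weed"]),
        crop_density=float(run.get("crop_density", 250.0)),
        weed_density=float(run.get("weed_density", 80.0)),
        crop_emergence_lag=int(run.get("crop_emergence_lag", 10)),
        weed_emergence_lag=int(run.get("weed_emergence_lag", 7)),
        constants=constants,
        latitude=float(run.get("latitude", 51.8)),
    )
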