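"""Dry-matter production, allocation, soil water and grain fill.

Absorbed PAR is converted to dry matter with a saturating light-response
curve applied layer by layer: instantaneous assimilation per unit leaf area
is ``amax·(1 − exp(−eps·I/amax))``, integrated over a sinusoidal diurnal
radiation course by 3-point Gaussian quadrature.  Leaves deep in a closed
canopy therefore run in the efficient linear part of the curve while sunlit
top layers saturate — the canopy-position dependence that makes height
competition matter.

New dry matter is split root/shoot on a development-dependent schedule
anchored at the cultivar's root weight ratio, then leaf/stem within the
shoot; after anthesis all net growth goes to grain (wheat) and a fixed
fraction of the anthesis leaf+stem mass is relocated to grain over the
grain-fill period while green area senesces linearly to zero.

Soil water is a single shared bucket: potential evapotranspiration is
derived from radiation, split into soil evaporation and canopy
transpiration by canopy cover, and a linear-ramp stress factor multiplies
assimilation once the store falls below a threshold fraction of plant-available
capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from .canopy import CultivarTraits, PlantStand
from .weather import WeatherDay

__all__ = [
    "ModelConstants",
    "SoilWater",
    "daily_assimilation",
    "temperature_factor",
    "water_balance_step",
    "partition_biomass",
    "senescence_grainfill_step",
]

# 3-point Gauss-Legendre nodes/weights on [0, 1]
_GAUSS3 = (
    (0.5 - math.sqrt(0.15), 5.0 / 18.0),
    (0.5, 8.0 / 18.0),
    (0.5 + math.sqrt(0.15), 5.0 / 18.0),
)

#: Root allocation fraction at anthesis (declines linearly from the
#: cultivar's initial root weight ratio at emergence).
ROOT_FRACTION_AT_ANTHESIS = 0.10

#: Leaf number at which stem extension starts (shoot growth is all leaf
#: before this).
STEM_EXTENSION_LEAF_NUMBER = 5.0

#: Leaf share of shoot growth retained at anthesis: leaf production slows
#: during stem extension but the flag leaves are still being built.
LEAF_SHARE_AT_ANTHESIS = 0.15


@dataclass(frozen=True)
class ModelConstants:
    """Species-independent model constants, all overridable per run.

    Units: ``amax`` g DM m⁻² leaf h⁻¹; ``eps`` g DM MJ⁻¹ PAR;
    ``grain_fill_dd`` dd; ``r_ref`` MJ m⁻² d⁻¹; soil stores in mm;
    ``seeds_per_gram`` weed seeds per g shoot biomass; ``t_ref_growth``
    the mean temperature excess over base (°C) above which assimilation is
    not temperature-limited.
    """

    amax: float = 1.5
    eps: float = 3.0
    gai_switch: float = 0.75
    final_leaf_number: float = 16.0
    grain_fill_dd: float = 750.0
    relocation_fraction: float = 0.25
    r_ref: float = 10.0
    pet_coefficient: float = 0.65
    soil_capacity: float = 150.0
    wilting_point: float = 0.0
    stress_threshold_fraction: float = 0.5
    seeds_per_gram: float = 150.0
    t_ref_growth: float = 10.0

    def __post_init__(self) -> None:
        if self.wilting_point >= self.soil_capacity:
            raise ValueError("wilting_point must be below soil_capacity")
        if not 0 < self.stress_threshold_fraction <= 1:
            raise ValueError("stress_threshold_fraction must be in (0, 1]")
        if not 0 <= self.relocation_fraction < 1:
            raise ValueError("relocation_fraction must be in [0, 1)")
        for key in ("amax", "eps", "gai_switch", "final_leaf_number", "grain_fill_dd",
                    "r_ref", "pet_coefficient", "soil_capacity", "seeds_per_gram",
                    "t_ref_growth"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be positive")


@dataclass(frozen=True)
class SoilWater:
    """Plant-available soil water store (mm)."""

    stored: float
    capacity: float = 150.0
    wilting: float = 0.0

    def __post_init__(self) -> None:
        if not self.wilting <= self.stored <= self.capacity:
            raise ValueError(
                f"soil store {self.stored} outside [{self.wilting}, {self.capacity}]"
            )


def daily_assimilation(
    absorbed_par_per_layer: Sequence[tuple[float, float]],
    daylength: float,
    constants: ModelConstants,
    water_factor: float = 1.0,
    temp_factor: float = 1.0,
) -> float:
    """Daily dry-matter production (g m⁻² ground d⁻¹) from absorbed PAR.

    ``absorbed_par_per_layer`` pairs each canopy layer's daily absorbed PAR
    (MJ m⁻² ground) with the species' green area in that layer
    (m² m⁻² ground).  The daily PAR is spread over daylight hours with a
    half-sine profile and expressed per unit green area, the saturating
    leaf response ``amax·(1 − exp(−eps·i/amax))`` is integrated by 3-point
    Gaussian quadrature, scaled back by the layer's area, summed across
    layers, and finally multiplied by the water and temperature stress
    factors (each in [0, 1]).
    """
    for name, fac in (("water_factor", water_factor), ("temp_factor", temp_factor)):
        if not 0.0 <= fac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if daylength <= 0:
        return 0.0
    amax, eps = constants.amax, constants.eps
    total = 0.0
    for par, area in absorbed_par_per_layer:
        if par < 0:
            raise ValueError("absorbed PAR must be non-negative")
        if par == 0.0 or area <= 0.0:
            continue
        # peak instantaneous flux per unit green area of the half-sine
        # whose daily integral is par/area
        peak = (par / area) * math.pi / (2.0 * daylength)
        day_sum = 0.0
        for node, weight in _GAUSS3:
            inst = peak * math.sin(math.pi * node)
            day_sum += weight * amax * (1.0 - math.exp(-eps * inst / amax))
        total += day_sum * daylength * area
    return total * water_factor * temp_factor


def temperature_factor(tmean: float, t_base: float, t_ref_growth: float) -> float:
    """Temperature limitation on assimilation, in [0, 1].

    Ramps linearly from 0 at the base temperature to 1 once the daily mean
    exceeds the base by ``t_ref_growth`` °C.  Cold days thus throttle
    light-driven growth the same way they throttle the thermal clocks —
    without this, a dim mid-winter day would grow more dry matter than the
    sink-limited demand can use.
    """
    if t_ref_growth <= 0:
        raise ValueError("t_ref_growth must be positive")
    return min(1.0, max(0.0, (tmean - t_base) / t_ref_growth))


def water_balance_step(
    soil: SoilWater,
    day: "WeatherDay",
    total_gai: float,
    constants: ModelConstants,
) -> tuple[SoilWater, float]:
    """Advance the soil bucket one day; return (new state, stress factor).

    Potential evapotranspiration is ``pet_coefficient × radiation / 2.45``
    mm (2.45 MJ kg⁻¹ latent heat), split by canopy cover exp(−0.5·GAI) into
    soil evaporation and transpiration demand.  Withdrawal stops at the
    wilting point and surplus beyond capacity drains.  The stress factor
    ramps linearly from 0 at wilting to 1 at ``stress_threshold_fraction``
    of plant-available capacity.
    """
    pet = constants.pet_coefficient * day.radiation / 2.45
    cover = 1.0 - math.exp(-0.5 * total_gai)
    evap_demand = pet * (1.0 - cover)
    transp_demand = pet * cover
    available = soil.stored + day.rain - soil.wilting
    demand = evap_demand + transp_demand
    actual = min(demand, max(0.0, available))
    stored = min(soil.capacity, max(soil.wilting, soil.stored + day.rain - actual))
    new_soil = replace(soil, stored=stored)
    span = constants.stress_threshold_fraction * (soil.capacity - soil.wilting)
    factor = (stored - soil.wilting) / span if span > 0 else 1.0
    return new_soil, min(1.0, max(0.0, factor))


def _root_fraction(traits: CultivarTraits, dev: float) -> float:
    """Root allocation fraction at relative development ``dev`` in [0, 1]."""
    return traits.rwr + (ROOT_FRACTION_AT_ANTHESIS - traits.rwr) * dev


def _leaf_share_of_shoot(leaf_number: float, final_leaf_number: float) -> float:
    """Leaf fraction of shoot growth: all leaf before stem extension, then
    declining linearly to a small floor at anthesis."""
    if leaf_number < STEM_EXTENSION_LEAF_NUMBER:
        return 1.0
    span = final_leaf_number - STEM_EXTENSION_LEAF_NUMBER
    frac = (leaf_number - STEM_EXTENSION_LEAF_NUMBER) / span
    return max(LEAF_SHARE_AT_ANTHESIS,
               1.0 - (1.0 - LEAF_SHARE_AT_ANTHESIS) * frac)


def marginal_area_per_dm(
    leaf_number: float,
    traits: CultivarTraits,
    constants: ModelConstants,
) -> float:
    """Green area gained per g of new dry matter at the current development.

    Combines the root/shoot split and the leaf/stem split with the specific
    leaf and stem areas; used to translate the sink-limited area demand
    into a dry-matter demand.
    """
    fln = traits.final_leaf_number or constants.final_leaf_number
    dev = min(1.0, leaf_number / fln)
    f_root = _root_fraction(traits, dev)
    f_leaf = _leaf_share_of_shoot(leaf_number, fln)
    return (1.0 - f_root) * (f_leaf * traits.sla + (1.0 - f_leaf) * traits.ssa)


def partition_biomass(
    dm: float,
    stand: PlantStand,
    traits: CultivarTraits,
    constants: ModelConstants,
    is_reproductive: bool = False,
    grain_bearing: bool = True,
    update_gai: bool = True,
) -> PlantStand:
    """Allocate one day's dry matter to the stand's pools (in place).

    Pre-anthesis the root fraction declines linearly from the trait RWR at
    emergence to 0.10 at anthesis; shoot growth is all leaf before stem
    extension (leaf number 5), then the leaf share declines linearly to
    zero at anthesis.  Post-anthesis all net growth goes to grain for a
    grain-bearing species, to stem otherwise.  Mass balance is exact.

    When ``update_gai`` is set (the source-limited phase) the green area
    index is recomputed from the pools as SLA·leaf + SSA·stem.
    """
    if dm < 0:
        raise ValueError("dm must be non-negative")
    if is_reproductive:
        if grain_bearing:
            stand.grain += dm
        else:
            stand.stem += dm
    else:
        leaf_no = stand.clock.leaf_number(traits) if stand.clock is not None else 0.0
        fln = traits.final_leaf_number or constants.final_leaf_number
        dev = min(1.0, leaf_no / fln)
        f_root = _root_fraction(traits, dev)
        shoot = dm * (1.0 - f_root)
        f_leaf = _leaf_share_of_shoot(leaf_no, fln)
        stand.root += dm * f_root
        stand.leaf += shoot * f_leaf
        stand.stem += shoot * (1.0 - f_leaf)
        if update_gai:
            stand.green_area_index = traits.sla * stand.leaf + traits.ssa * stand.stem
    return stand


def senescence_grainfill_step(
    stand: PlantStand,
    tt_post_anthesis: float,
    dtt: float,
    anthesis_shoot: float,
    anthesis_gai: float,
    constants: ModelConstants,
    grain_bearing: bool = True,
    fill_dd: float | None = None,
) -> PlantStand:
    """One reproductive-phase day: relocation to grain and green-area decline.

    A total of ``relocation_fraction × anthesis_shoot`` (leaf+stem mass at
    anthesis) moves to grain, spread uniformly over the grain-fill span of
    post-anthesis thermal time and drawn from leaf and stem in proportion
    to their current sizes; relocation conserves mass and pools never go
    negative.  Green area declines linearly from its anthesis value to zero
    at maturity (for every species — senescence is not grain-specific).
    ``fill_dd`` overrides the run-level grain-fill duration for species
    that senesce on their own schedule.
    """
    fill = fill_dd if fill_dd is not None else constants.grain_fill_dd
    if grain_bearing and constants.relocation_fraction > 0:
        done_before = min(tt_post_anthesis - dtt, fill)
        done_now = min(tt_post_anthesis, fill)
        move = constants.relocation_fraction * anthesis_shoot * (done_now - max(0.0, done_before)) / fill
        move = min(move, stand.leaf + stand.stem)
        pool = stand.leaf + stand.stem
        if pool > 0 and move > 0:
            stand.leaf -= move * stand.leaf / pool
            stand.stem -= move * stand.stem / pool
            stand.grain += move
    stand.green_area_index = anthesis_gai * max(0.0, 1.0 - tt_post_anthesis / fill)
    return stand
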