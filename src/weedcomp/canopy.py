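"""Canopy structure and light competition.

Green area dynamics have two regimes.  Before the stand closes, each
species expands its green area index (GAI) exponentially on its own
effective-day-degree clock — growth is *sink* limited.  Once the combined
GAI of all species reaches a threshold (0.75 by default) growth becomes
*source* limited: the canopy is cut into horizontal layers at every distinct
plant height and daily photosynthetically active radiation is attenuated
top-down through the layers by Beer's law, each species taking a share of
the interception in a layer proportional to its extinction-weighted green
area there.  Height growth follows a logistic curve in photothermal time, so
a species that gains height early shades its neighbour out of the
best-lit layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .phenology import DevStage, PhenoClock

__all__ = [
    "CultivarTraits",
    "PlantStand",
    "CanopyLayer",
    "LightPartition",
    "height_at",
    "sink_limited_gai",
    "competition_switch",
    "build_layers",
    "partition_light",
]

#: Combined green area index at which the model switches from sink-limited
#: exponential expansion to source-limited light competition.
GAI_SWITCH_DEFAULT = 0.75


@dataclass(frozen=True)
class CultivarTraits:
    """Eco-physiological trait set for one species or cultivar.

    Parameters
    ----------
    rwr
        Root weight ratio: fraction of new dry matter sent below ground at
        emergence (declines with development).
    ssa, sla
        Specific stem / leaf area (m² per g dry mass); convert biomass pools
        back to green area.
    phyllochron
        Thermal-time interval between successive leaf tips (dd leaf⁻¹);
        controls developmental speed and hence time to anthesis.
    rgr_ga
        Relative growth rate of green area per effective day degree during
        the sink-limited phase.
    l0
        Initial green area per plant at emergence (cm²).
    height_a, height_c, height_b, height_m
        Logistic height curve: initial height, asymptote (cm), rate constant
        (per photothermal unit) and photothermal time of the inflexion.
    k_ext
        Beer's-law light extinction coefficient.
    t_base
        Base temperature for all thermal clocks (°C).
    """

    name: str
    rwr: float
    ssa: float
    phyllochron: float
    sla: float
    rgr_ga: float
    l0: float
    height_a: float
    height_c: float
    height_b: float
    height_m: float
    k_ext: float = 0.60
    t_base: float = 0.0
    #: species-specific final leaf number triggering anthesis; None defers
    #: to the run-level model constants
    final_leaf_number: float | None = None
    #: long-day flowering cue: anthesis once the (increasing) daylength
    #: reaches this many hours, whichever of the two triggers fires first.
    #: None disables the photoperiod cue.
    anthesis_daylength: float | None = None
    #: thermal time from anthesis to complete senescence; None defers to
    #: the run-level grain-fill duration
    senescence_dd: float | None = None

    def __post_init__(self) -> None:
        if self.final_leaf_number is not None and self.final_leaf_number <= 0:
            raise ValueError(f"{self.name}: final_leaf_number must be positive")
        if self.anthesis_daylength is not None and not 0 < self.anthesis_daylength < 24:
            raise ValueError(f"{self.name}: anthesis_daylength must be in (0, 24)")
        if self.senescence_dd is not None and self.senescence_dd <= 0:
            raise ValueError(f"{self.name}: senescence_dd must be positive")
        positive = {
            "rwr": self.rwr,
            "ssa": self.ssa,
            "phyllochron": self.phyllochron,
            "sla": self.sla,
            "rgr_ga": self.rgr_ga,
            "l0": self.l0,
            "height_a": self.height_a,
            "height_c": self.height_c,
            "height_b": self.height_b,
            "height_m": self.height_m,
            "k_ext": self.k_ext,
        }
        for key, val in positive.items():
            if not val > 0:
                raise ValueError(f"{self.name}: trait {key} must be positive, got {val}")
        if not self.rwr < 1:
            raise ValueError(f"{self.name}: rwr must be < 1, got {self.rwr}")
        if not self.height_a < self.height_c:
            raise ValueError(f"{self.name}: height_a must be below asymptote height_c")
        if not self.sla > self.ssa:
            raise ValueError(f"{self.name}: sla must exceed ssa")


@dataclass
class PlantStand:
    """Daily state of one species in the mixed stand.

    Biomass pools are g dry matter per m² ground; ``green_area_index`` is
    m² green (leaf + stem) area per m² ground; ``height`` is cm.
    """

    species: str
    traits: CultivarTraits
    density: float
    root: float = 0.0
    leaf: float = 0.0
    stem: float = 0.0
    grain: float = 0.0
    green_area_index: float = 0.0
    height: float = 0.0
    clock: "PhenoClock | None" = None
    stage: "DevStage | None" = None

    @property
    def above_ground(self) -> float:
        """Above-ground dry biomass (leaf + stem + grain), g m⁻²."""
        return self.leaf + self.stem + self.grain

    @property
    def total_biomass(self) -> float:
        return self.root + self.leaf + self.stem + self.grain


@dataclass(frozen=True)
class CanopyLayer:
    """Horizontal canopy slab between two heights with per-species area."""

    z_low: float
    z_high: float
    area: Mapping[str, float]  # species -> green area index within this slab

    def __post_init__(self) -> None:
        if not self.z_low < self.z_high:
            raise ValueError(f"layer bounds inverted: [{self.z_low}, {self.z_high}]")


@dataclass(frozen=True)
class LightPartition:
    """Outcome of one day's light partitioning (MJ PAR m⁻² d⁻¹)."""

    absorbed: Mapping[str, float]
    absorbed_by_layer: Mapping[str, tuple[float, ...]]
    transmitted: float


def height_at(ptt: float, traits: CultivarTraits) -> float:
    """Plant height (cm) at accumulated photothermal time ``ptt``.

    Logistic: h = a + (c − a) / (1 + exp(−b·(ptt − m))); strictly
    increasing from just above ``a`` towards the asymptote ``c``.
    """
    if ptt < 0:
        raise ValueError("ptt must be non-negative")
    a, c, b, m = traits.height_a, traits.height_c, traits.height_b, traits.height_m
    return a + (c - a) / (1.0 + math.exp(-b * (ptt - m)))


def sink_limited_gai(traits: CultivarTraits, density: float, edd: float) -> float:
    """Green area index during the sink-limited phase.

    GAI = density × L0 × exp(RGR_GA × edd), with L0 converted from cm² per
    plant to m² (× 1e-4).
    """
    if edd < 0:
        raise ValueError("edd must be non-negative")
    return density * traits.l0 * 1e-4 * math.exp(traits.rgr_ga * edd)


def competition_switch(total_gai: float, threshold: float = GAI_SWITCH_DEFAULT, latched: bool = False) -> bool:
    """True once the combined canopy has closed (total GAI ≥ threshold).

    The switch latches: pass the previous day's value as ``latched`` and the
    stand stays source-limited even if senescence later drops GAI below the
    threshold.
    """
    if total_gai < 0:
        raise ValueError("total_gai must be non-negative")
    return latched or total_gai >= threshold


def build_layers(stands: Sequence[PlantStand]) -> list[CanopyLayer]:
    """Stratify the mixed canopy into horizontal layers.

    Layer boundaries sit at 0 and at every distinct stand height.  Each
    species' green area is spread uniformly from the ground to its own
    height, so a slab of thickness t contributes GAI × t / height.  Species
    with zero green area are ignored; a stand with green area but no height
    is an error.

    Layers are returned bottom-up by height.
    """
    active = []
    for s in stands:
        if s.green_area_index < 0:
            raise ValueError(f"{s.species}: negative green area")
        if s.green_area_index > 0:
            if s.height <= 0:
                raise ValueError(f"{s.species}: green area {s.green_area_index} with non-positive height")
            active.append(s)
    if not active:
        return []
    bounds = sorted({0.0} | {s.height for s in active})
    layers = []
    for z0, z1 in zip(bounds, bounds[1:]):
        area = {}
        for s in active:
            if s.height >= z1 - 1e-12:
                area[s.species] = s.green_area_index * (z1 - z0) / s.height
        layers.append(CanopyLayer(z0, z1, area))
    return layers


def partition_light(
    layers: Sequence[CanopyLayer],
    i0: float,
    k_ext: Mapping[str, float],
) -> LightPartition:
    """Partition incident PAR among species by layered Beer's law.

    Radiation enters the top layer; within a layer the intercepted fraction
    is 1 − exp(−Σ_s k_s·A_s) and each species absorbs a share
    k_s·A_s / Σ_j k_j·A_j of it.  What leaves a layer enters the next one
    down; the remainder reaches the soil.  Absorbed + transmitted equals
    ``i0`` up to floating-point rounding.
    """
    if i0 < 0:
        raise ValueError("incident PAR must be non-negative")
    species = sorted({sp for layer in layers for sp in layer.area})
    absorbed = {sp: 0.0 for sp in species}
    by_layer: dict[str, list[float]] = {sp: [] for sp in species}
    i_in = i0
    # top-down: iterate layers sorted by upper bound, highest first
    ordered = sorted(layers, key=lambda L: L.z_high, reverse=True)
    for layer in ordered:
        weighted = {}
        for sp, a in layer.area.items():
            if a < 0:
                raise ValueError(f"{sp}: negative layer area")
            weighted[sp] = k_ext[sp] * a
        total_ka = sum(weighted.values())
        if total_ka > 0:
            intercepted = i_in * (1.0 - math.exp(-total_ka))
            for sp in species:
                share = intercepted * weighted.get(sp, 0.0) / total_ka
                absorbed[sp] += share
                by_layer[sp].append(share)
            i_in -= intercepted
        else:
            for sp in species:
                by_layer[sp].append(0.0)
    # by_layer was collected top-down; flip to match bottom-up layer order
    return LightPartition(
        absorbed=absorbed,
        absorbed_by_layer={sp: tuple(reversed(v)) for sp, v in by_layer.items()},
        transmitted=i_in,
    )
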