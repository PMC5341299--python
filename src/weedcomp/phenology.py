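"""Biological-time clocks and developmental stage switches.

Each species carries three accumulating clocks from emergence onwards —
thermal time (dd), photothermal time and effective day degrees — plus a
derived leaf number (thermal time / phyllochron).  Development is
one-directional: pre-emergence → vegetative → reproductive (post-anthesis)
→ mature.  Anthesis is triggered when the leaf number reaches a final leaf
number (default 11), which makes the cultivar phyllochron consequential: a
faster-leafing cultivar flowers at less accumulated thermal time.  Maturity
follows a fixed amount of post-anthesis thermal time (grain fill).
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, replace

from .canopy import CultivarTraits
from .weather import (
    WeatherDay,
    effective_day_degrees_increment,
    photoperiod,
    photothermal_increment,
    thermal_time_increment,
)

__all__ = ["PhenoClock", "DevStage", "advance_clock", "emergence_day", "stage_of"]

FINAL_LEAF_NUMBER_DEFAULT = 16.0
GRAIN_FILL_DD_DEFAULT = 750.0


class DevStage(enum.IntEnum):
    """Developmental stages in their one-directional order."""

    PRE_EMERGENCE = 0
    VEGETATIVE = 1
    REPRODUCTIVE = 2
    MATURE = 3


@dataclass(frozen=True)
class PhenoClock:
    """Accumulated biological time since emergence.

    ``tt`` thermal time (dd); ``ptt`` photothermal units; ``edd`` effective
    day degrees; ``tt_post_anthesis`` thermal time since anthesis (0 before).
    All are non-negative and non-decreasing.
    """

    tt: float = 0.0
    ptt: float = 0.0
    edd: float = 0.0
    tt_post_anthesis: float = 0.0

    def leaf_number(self, traits: CultivarTraits) -> float:
        return self.tt / traits.phyllochron


def advance_clock(
    clock: PhenoClock,
    day: WeatherDay,
    traits: CultivarTraits,
    latitude: float = 51.8,
    r_ref: float = 10.0,
    anthesis_reached: bool = False,
) -> PhenoClock:
    """Advance all clocks by one day of weather.

    ``anthesis_reached`` routes the day's thermal time into the
    post-anthesis accumulator as well, which paces grain fill and
    senescence.
    """
    dd = thermal_time_increment(day.tmin, day.tmax, traits.t_base)
    daylength = photoperiod(day.date.timetuple().tm_yday, latitude)
    return PhenoClock(
        tt=clock.tt + dd,
        ptt=clock.ptt + photothermal_increment(dd, daylength),
        edd=clock.edd + effective_day_degrees_increment(dd, day.radiation, r_ref),
        tt_post_anthesis=clock.tt_post_anthesis + (dd if anthesis_reached else 0.0),
    )


def emergence_day(sowing_date: _dt.date, lag_days: int) -> _dt.date:
    """Date of emergence: sowing date plus a fixed whole-day lag."""
    if lag_days < 0:
        raise ValueError("emergence lag must be non-negative")
    return sowing_date + _dt.timedelta(days=lag_days)


def stage_of(
    clock: PhenoClock,
    traits: CultivarTraits,
    final_leaf_number: float = FINAL_LEAF_NUMBER_DEFAULT,
    grain_fill_dd: float = GRAIN_FILL_DD_DEFAULT,
) -> DevStage:
    """Developmental stage implied by a clock (for an emerged plant).

    Vegetative until the leaf number reaches ``final_leaf_number``
    (anthesis); mature once ``grain_fill_dd`` of post-anthesis thermal time
    has accumulated.
    """
    if clock.leaf_number(traits) < final_leaf_number:
        return DevStage.VEGETATIVE
    if clock.tt_post_anthesis < grain_fill_dd:
        return DevStage.REPRODUCTIVE
    return DevStage.MATURE
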