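"""Daily weather series and the derived biological-time driving variables.

The simulator is driven by four daily records — minimum and maximum air
temperature (°C), global solar radiation (MJ m⁻² d⁻¹) and rainfall (mm) —
from which three clocks are derived:

* **thermal time** (degree-days above a base temperature),
* **photothermal time** (thermal time weighted by daylength / 24), which
  drives logistic height growth, and
* **effective day degrees** (thermal time damped by a saturating radiation
  modifier), the biological clock of early, sink-limited leaf-area growth.

Weather CSV schema (exact header)::

    date,tmin_c,tmax_c,radiation_mj_m2,rain_mm

with ISO-8601 dates on strictly consecutive days.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Union

import numpy as np
import pandas as pd

__all__ = [
    "WeatherDay",
    "WeatherSeries",
    "WeatherValidationError",
    "read_weather",
    "write_weather",
    "photoperiod",
    "thermal_time_increment",
    "photothermal_increment",
    "effective_day_degrees_increment",
]

WEATHER_COLUMNS = ["date", "tmin_c", "tmax_c", "radiation_mj_m2", "rain_mm"]

#: Default reference radiation (MJ m⁻² d⁻¹) above which a day counts at its
#: full thermal-time value in the effective-day-degrees clock.
DEFAULT_R_REF = 10.0


class WeatherValidationError(ValueError):
    """Raised when a weather source violates the schema or its invariants."""


@dataclass(frozen=True)
class WeatherDay:
    """One day of driving weather.

    Invariants: ``tmin <= tmax``, ``radiation >= 0``, ``rain >= 0``.
    """

    date: _dt.date
    tmin: float
    tmax: float
    radiation: float
    rain: float

    def __post_init__(self) -> None:
        if self.tmin > self.tmax:
            raise WeatherValidationError(
                f"{self.date}: tmin ({self.tmin}) exceeds tmax ({self.tmax})"
            )
        if self.radiation < 0:
            raise WeatherValidationError(f"{self.date}: negative radiation {self.radiation}")
        if self.rain < 0:
            raise WeatherValidationError(f"{self.date}: negative rainfall {self.rain}")

    @property
    def tmean(self) -> float:
        """Daily mean temperature, the tmin/tmax arithmetic mean (°C)."""
        return 0.5 * (self.tmin + self.tmax)


@dataclass
class WeatherSeries:
    """A contiguous run of daily weather at one site.

    Days must be strictly consecutive (no gaps, no duplicates); latitude is
    in decimal degrees north, in [-90, 90].
    """

    days: list[WeatherDay]
    latitude: float = 51.8

    _index: dict[_dt.date, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise WeatherValidationError(f"latitude {self.latitude} outside [-90, 90]")
        for prev, cur in zip(self.days, self.days[1:]):
            gap = (cur.date - prev.date).days
            if gap != 1:
                if gap == 0:
                    raise WeatherValidationError(f"duplicate date {cur.date}")
                missing = prev.date + _dt.timedelta(days=1)
                raise WeatherValidationError(f"gap at {missing.isoformat()}")
        self._index = {d.date: i for i, d in enumerate(self.days)}

    def __len__(self) -> int:
        return len(self.days)

    def __iter__(self) -> Iterator[WeatherDay]:
        return iter(self.days)

    @property
    def start(self) -> _dt.date:
        return self.days[0].date

    @property
    def end(self) -> _dt.date:
        return self.days[-1].date

    def day(self, date: _dt.date) -> WeatherDay:
        try:
            return self.days[self._index[date]]
        except KeyError:
            raise KeyError(f"date {date} not covered by series [{self.start}..{self.end}]") from None

    def __contains__(self, date: _dt.date) -> bool:
        return date in self._index

    def slice(self, start: _dt.date, end: _dt.date) -> "WeatherSeries":
        """Sub-series covering [start, end] inclusive."""
        i, j = self._index[start], self._index[end]
        return WeatherSeries(self.days[i : j + 1], self.latitude)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": [d.date.isoformat() for d in self.days],
                "tmin_c": [d.tmin for d in self.days],
                "tmax_c": [d.tmax for d in self.days],
                "radiation_mj_m2": [d.radiation for d in self.days],
                "rain_mm": [d.rain for d in self.days],
            }
        )


def read_weather(source: Union[str, Path, IO[str]], latitude: float = 51.8) -> WeatherSeries:
    """Read and validate a weather CSV (see module docstring for the schema).

    Raises :class:`WeatherValidationError` naming the offending row for a
    missing column, an empty file, non-consecutive dates, ``tmin > tmax`` or
    negative radiation/rain.
    """
    try:
        frame = pd.read_csv(source, dtype={"date": str})
    except pd.errors.EmptyDataError:
        raise WeatherValidationError("weather source is empty") from None
    missing = [c for c in WEATHER_COLUMNS if c not in frame.columns]
    if missing:
        raise WeatherValidationError(f"missing column(s): {', '.join(missing)}")
    if len(frame) == 0:
        raise WeatherValidationError("weather source has a header but no rows")
    days = []
    for row_no, rec in enumerate(frame.itertuples(index=False), start=2):
        try:
            date = _dt.date.fromisoformat(rec.date)
        except ValueError:
            raise WeatherValidationError(f"row {row_no}: unparseable date {rec.date!r}") from None
        try:
            days.append(
                WeatherDay(
                    date,
                    float(rec.tmin_c),
                    float(rec.tmax_c),
                    float(rec.radiation_mj_m2),
                    float(rec.rain_mm),
                )
            )
        except WeatherValidationError as exc:
            raise WeatherValidationError(f"row {row_no}: {exc}") from None
    return WeatherSeries(days, latitude)


def write_weather(series: WeatherSeries, target: Union[str, Path, IO[str]]) -> None:
    """Write a series back to the canonical CSV schema."""
    series.to_frame().to_csv(target, index=False)


def photoperiod(day_of_year: int, latitude: float) -> float:
    """Astronomical daylength in hours (sunrise to sunset, centre of disc).

    Uses the standard solar-declination + hour-angle formula with the
    declination approximated by a cosine of the day of year (minimum at the
    December solstice).  The result is clamped to [0, 24] so polar day and
    night are handled without error.
    """
    decl = math.radians(-23.44 * math.cos(2.0 * math.pi * (day_of_year + 10) / 365.25))
    lat = math.radians(latitude)
    cos_ha = -math.tan(lat) * math.tan(decl)
    if cos_ha <= -1.0:
        return 24.0
    if cos_ha >= 1.0:
        return 0.0
    return 2.0 * math.degrees(math.acos(cos_ha)) / 15.0


def thermal_time_increment(tmin: float, tmax: float, t_base: float = 0.0) -> float:
    """Degree-days accumulated in one day: max(0, mean temperature − base)."""
    return max(0.0, 0.5 * (tmin + tmax) - t_base)


def photothermal_increment(dd: float, daylength: float) -> float:
    """Photothermal units for one day: degree-days weighted by daylength/24."""
    return dd * daylength / 24.0


def effective_day_degrees_increment(dd: float, radiation: float, r_ref: float = DEFAULT_R_REF) -> float:
    """Effective day degrees: thermal time scaled by a saturating radiation
    modifier min(1, radiation / r_ref).

    Dim, short days early in an autumn-sown season therefore advance the
    leaf-area clock more slowly than the raw thermal clock; bright days count
    in full.
    """
    if r_ref <= 0:
        raise ValueError("r_ref must be positive")
    return dd * min(1.0, radiation / r_ref)
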