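"""Generate synthetic weather years and inspect their climate statistics.

The generator emulates a temperate lowland-UK site: a seasonal
temperature sinusoid with AR(1) day-to-day noise, seasonal radiation with
daily cloudiness, and Markov-chain rainfall.  Cold- and warm-year presets
shift the annual mean by -/+1.5 degC.
"""

import datetime as dt

import numpy as np

from weedcomp.synthetic import generate_weather, preset_climatologies
from weedcomp.weather import thermal_time_increment, write_weather

for name, clim in preset_climatologies().items():
    series = generate_weather(clim, dt.date(2005, 9, 1), 334, seed=42)
    tmean = np.mean([d.tmean for d in series])
    rain = sum(d.rain for d in series)
    wet_days = sum(d.rain > 0 for d in series)
    tt = sum(thermal_time_increment(d.tmin, d.tmax) for d in series)
    print(
        f"{name:19s} mean T {tmean:5.2f} C | rain {rain:6.0f} mm on {wet_days:3d} days"
        f" | thermal time Sep-Jul {tt:6.0f} dd"
    )

series = generate_weather(preset_climatologies()["rothamsted_default"],
                          dt.date(2005, 9, 1), 334, seed=42)
write_weather(series, "scratch_weather_2005.csv")
print("\nwrote scratch_weather_2005.csv (delete when done)")
# Accumulated thermal time is the season's biological-time budget; its
# spread across seeds drives the year-to-year spread in competition outcomes.
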