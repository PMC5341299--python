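"""Diminishing returns of crop sowing density, and the density at which a
weakly competitive cultivar matches a strongly competitive one.

Runs Duxford and KWS Santiago at six densities over ten synthetic weather
years, fits the rectangular hyperbola yl = A / (1 + B*density) to each
mean response, and solves for the Santiago density equivalent to Duxford
at 150 plants/m2.
"""

import datetime as dt

from weedcomp.experiments import (
    FactorialGrid,
    equivalent_density,
    fit_hyperbola,
    run_factorial,
    summarize,
)
from weedcomp.synthetic import cultivar_fixtures, generate_weather, preset_climatologies

fixtures = cultivar_fixtures()
clim = preset_climatologies()["rothamsted_default"]
years = {y: generate_weather(clim, dt.date(2005, 9, 1), 400, seed=y) for y in range(1, 11)}

grid = FactorialGrid(
    densities=[100, 200, 300, 400, 500, 600],
    sowing_dates=[dt.date(2005, 9, 20)],
    cultivars=[fixtures["Duxford"], fixtures["KWS Santiago"]],
    weather_set=years,
    weed_traits=fixtures["blackgrass"],
)
table = run_factorial(grid)

for name in ("Duxford", "KWS Santiago"):
    curve = summarize(table[table.cultivar == name], ["density"], "yield_loss")
    fit = fit_hyperbola(curve["density"], curve["mean"])
    print(f"{name:13s} mean loss by density:")
    for _, row in curve.iterrows():
        print(f"    {row.density:4.0f} plants/m2  {row['mean']:5.1f} % (se {row.se:.2f})")
    print(f"    hyperbola fit: A={fit.a:.1f}, B={fit.b:.4f}")

eq = equivalent_density(table, ("Duxford", 150.0), "KWS Santiago")
flag = " (beyond the simulated range)" if eq.extrapolated else ""
print(
    f"\nto match Duxford at 150 plants/m2 ({eq.reference_loss:.1f} % loss), "
    f"KWS Santiago must be sown at ~{eq.value:.0f} plants/m2{flag}"
)
# Each added crop plant suppresses the weed less than the one before
# (B > 0), so very high seed rates cannot substitute for cultivar choice.
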