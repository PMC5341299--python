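# weedcomp

Eco-physiological simulation of competition between winter wheat
(*Triticum aestivum*) and black-grass (*Alopecurus myosuroides*), built to
ask a practical integrated-weed-management question: **how much weed
suppression do the cultural levers — sowing density, sowing date and
cultivar choice — buy, alone and in combination, across variable weather
years?** Black-grass is the primary target of non-chemical control in
North-West European cereals because it has evolved resistance to most
herbicide groups; field trials of lever combinations are slow and
expensive, so the package answers the question *in silico*.

## The model

A daily-time-step, two-species canopy competition model in the INTERCOM
tradition:

* **Biological time.** Each species accumulates thermal time
  (tt, degree-days above its base temperature), photothermal time
  (ptt = tt × daylength/24, driving logistic height growth
  `h = a + (c − a)/(1 + e^{−b(ptt − m)})`), and effective day degrees
  (edd = tt × min(1, radiation/r_ref), the clock of early leaf-area
  growth). Leaf number is tt divided by the cultivar phyllochron; anthesis
  follows a final leaf number (or a long-day cue for the weed), maturity a
  fixed grain-fill duration.
* **Two growth regimes switched by canopy closure.** While the combined
  green area index (GAI) is below 0.75 the species do not interact: each
  grows by the lesser of its sink-limited demand (exponential in edd at
  rate RGR_GA) and the light supply through its own canopy. Once total
  GAI ≥ 0.75, the canopy is cut into horizontal layers at every distinct
  plant height, PAR is attenuated top-down by Beer's law
  (`1 − exp(−Σ k_s·A_s)` per layer, species shares ∝ k_s·A_s), and each
  species converts its absorbed PAR to dry matter through a saturating
  leaf response integrated over a sinusoidal diurnal cycle by 3-point
  Gaussian quadrature.
* **Allocation and grain.** New dry matter is split root/leaf/stem on a
  development-dependent schedule anchored at the cultivar root weight
  ratio; green area follows the pools through the specific leaf and stem
  areas (GAI = SLA·leaf + SSA·stem). After anthesis, new assimilate plus a
  relocated fraction of the anthesis leaf+stem mass fills grain while the
  canopy senesces. A shared soil-water bucket turns radiation-driven
  evapotranspiration into a [0, 1] stress factor.
* **Outcomes.** Every weedy season is paired with a weed-free season on
  identical weather; percentage yield loss is
  `100 × (Y_weedfree − Y_weedy)/Y_weedfree`, and weed seed return is
  proportional to weed shoot biomass at harvest.

The three wheat parameter sets (Consort, Duxford, KWS Santiago) are
published cultivar parameterisations; Duxford is the strongly
weed-suppressive cultivar (fast leaf appearance, high specific leaf area,
vigorous early area growth), KWS Santiago the weakly suppressive one. The
black-grass trait set is a documented stand-in (see `docs/methods.md`).
Synthetic weather emulates a temperate lowland-UK site at 51.8 °N.

## Worked example

`examples/single_season.py` sows Duxford at 300 plants m⁻² on
20 September with 80 black-grass plants m⁻² under one seeded synthetic
weather year:

```
harvest date            2006-06-16
weed-free yield           5.46 t/ha
yield with weed           4.52 t/ha
yield loss                17.2 %
weed shoot biomass         317 g/m2
weed seed return         47543 seeds/m2
peak crop green area      2.82 m2/m2
```

The weed cost this stand 0.94 t/ha (17.2 % of its weed-free potential)
and returned ~48,000 seeds m⁻² to the seed bank. The other examples show
the density response with its rectangular-hyperbola fit and equivalence
point (`density_response.py`), the 2×2×2 factorial ANOVA over ten weather
years (`sowing_date_and_cultivar.py`), and the weather generator's
climate statistics (`weather_generator.py`).

Shell entry points for single runs exist too:

```bash
weedcomp synth-weather --preset rothamsted_default --years 10 --seed 42 --out met/
weedcomp simulate --config run.toml --weather met/rothamsted_default_2005.csv \
    --out result.json --trajectory daily.csv
```

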