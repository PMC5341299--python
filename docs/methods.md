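# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the numerical choices, what the synthetic data do
and do not emulate, and the design decisions taken where the design was
genuinely open.

## Model structure

One simulated season couples two plant stands — a winter-wheat cultivar
and black-grass (*Alopecurus myosuroides*) — through light and soil water
in daily steps from sowing to crop maturity. Three clocks drive
everything:

| clock | definition | role |
|---|---|---|
| thermal time, tt (dd) | Σ max(0, T̄ − T_base) | leaf number (tt/phyllochron), anthesis, grain fill |
| photothermal time, ptt | Σ dd·daylength/24 | logistic height growth |
| effective day degrees, edd | Σ dd·min(1, R/r_ref) | sink-limited area expansion |

Daylength is the standard solar-declination/hour-angle daylength with a
cosine declination approximation (checked against the CBM daylength model
to < 0.2 h); it is clamped to [0, 24] at polar latitudes. The daily mean
temperature is the tmin/tmax arithmetic mean. `r_ref` (default
10 MJ m⁻² d⁻¹) is the radiation level above which a day counts in full
toward the area-expansion clock; dim autumn days advance it at roughly
half speed.

### The two growth regimes

**Open canopy (total GAI < 0.75).** The species do not interact at all.
Each day a species grows by the *minimum* of

* its sink-limited demand — its current green area times
  `expm1(RGR_GA · Δedd)`, converted to a dry-matter demand through the
  marginal area per unit dry matter at its current development, and
* its light supply — the PAR absorbed through its *own, single-species*
  canopy, converted by the leaf-level light response below.

Early in autumn the demand term binds (growth is exponential, the classic
sink-limited phase); as the stand thickens or light fades the supply term
takes over smoothly. Treating the exponential as a demand rather than a
trajectory keeps growth continuous across the competition switch and
gives sparse, late-sown stands that never reach canopy closure a sensible
season instead of a degenerate one.

**Closed canopy (total GAI ≥ 0.75, latched).** Canopy closure starts
competition. The mixed canopy is stratified into horizontal layers with
boundaries at 0 and at every distinct plant height; each species' area is
spread uniformly from the ground to its height (the simplest conserving
profile; a hook exists for alternatives). PAR (0.5 × global radiation)
enters the top layer; a layer intercepts `1 − exp(−Σ_s k_s A_s)` of what
reaches it and species absorb shares proportional to `k_s A_s`. The
scheme agrees with a 1000-sublayer continuous attenuation to < 0.5 %.

### Assimilation

Absorbed PAR is converted per layer: the daily absorbed flux per unit
green area is spread over daylight hours as a half-sine, the saturating
response `amax·(1 − exp(−eps·i/amax))` is integrated by 3-point
Gauss–Legendre quadrature (within 1 % of a 1000-step integration), scaled
back by the layer's area and summed. Shaded layers therefore run in the
efficient linear regime (limit `eps × absorbed PAR`) while sunlit tops
saturate — the reason height and canopy position matter. Two stress
factors multiply the result: the soil-water factor and a temperature
factor ramping 0→1 over the first `t_ref_growth` = 10 °C of daily mean
temperature. The temperature factor embodies "temperature is
growth-limiting": without it, mid-winter light would grow more dry matter
than cold-season physiology can use.

### Allocation, grain fill, senescence

The root fraction declines linearly from the cultivar's root weight ratio
(RWR) at emergence to 0.10 at anthesis; shoot growth is all leaf before
leaf 5, then the leaf share declines linearly to a floor of 0.15 at
anthesis (wheat keeps building flag leaves during stem extension; with a
floor of zero the simulated crop cannot reach a realistic spring canopy).
Green area follows the pools: GAI = SLA·leaf + SSA·stem. After anthesis
all net growth goes to grain (wheat) or stem (weed); additionally a
fraction (default 0.25) of the anthesis leaf+stem mass is relocated to
grain, spread uniformly over the grain-fill thermal time, drawn from leaf
and stem pro rata. Green area declines linearly to zero over the same
span. Mass balance is exact to rounding in every step.

### Soil water

A single shared bucket (default 150 mm plant-available, starting full at
autumn sowing). Potential evapotranspiration is
`0.65 × radiation / 2.45` mm d⁻¹, split into soil evaporation and
transpiration by canopy cover `1 − exp(−0.5·GAI)`; withdrawal stops at
wilting and surplus drains at capacity. The stress factor ramps linearly
from 0 at wilting to 1 at half of plant-available capacity. Because the
total daily withdrawal equals PET regardless of canopy, the store — and
hence the stress factor — is provably identical in the weedy and
weed-free members of a pair, which keeps the weed-free control clean.

### Phenology

Anthesis triggers when leaf number reaches the final leaf number
(default 16; with the published phyllochrons this puts wheat anthesis in
mid-April–May and maturity in June–July, the real winter-wheat calendar —
smaller values push anthesis into winter, before canopy closure, and the
season degenerates). A species may instead carry a long-day cue
(`anthesis_daylength`): the weed heads when daylength first exceeds
14.5 h (≈ 3 May at 51.8 °N), whichever trigger fires first. Maturity
follows `grain_fill_dd` (default 750 dd) or a species override
(`senescence_dd`). Stage order is strictly one-directional.

## Parameterisation

The three wheat trait sets (Consort, Duxford, KWS Santiago) are published
values: RWR, SSA, phyllochron, SLA, RGR_GA, L₀ and the four height-curve
parameters. The height parameter printed as a "maximum growth rate" is
used as the logistic rate constant (ptt⁻¹): with c ≈ 78 cm and m ≈ 624
ptt, a value of 0.0085 is only dimensionally consistent in that role. L₀
(printed in cm) is read as cm² of green area per seedling.

The black-grass set is a constructed stand-in with the qualitative
features that make the species the problem it is, not a published
parameterisation:

* faster relative area growth than any of the wheats (RGR_GA = 0.013 per
  edd) on a *warmer-based* clock (T_base = 2 °C vs 0 °C for wheat) — its
  competitive edge therefore compounds in warm autumns and melts away in
  cold ones, which is the mechanism behind both the sowing-date and the
  between-year effects;
* vigorous establishment (L₀ = 1.2 cm² per plant, covering seedling size
  plus early tillering: at 80 plants m⁻² the weed contributes enough
  early area that canopy closure is weed-driven rather than
  cultivar-driven);
* an overwintering rosette of real stature (height curve a = 4 cm,
  c = 80 cm, b = 0.006 ptt⁻¹, m = 700 ptt) that holds its place in the
  lower canopy;
* long-day flowering in early May and green tissue persisting ~650 dd
  (seed shed around mid-July), so its growth window is anchored to the
  calendar, not the sowing date;
* high specific leaf area (0.045 m² g⁻¹), lower extinction coefficient
  (k = 0.50 vs 0.60), lower root allocation (RWR = 0.60).

Every one of these is a `CultivarTraits` field and can be overridden per
run, from Python or from the TOML run configuration.

Model constants and defaults: amax = 1.5 g DM m⁻² leaf h⁻¹, eps = 3.0
g DM MJ⁻¹ PAR, GAI switch 0.75, final leaf number 16, grain fill 750 dd,
relocation fraction 0.25, r_ref 10 MJ m⁻² d⁻¹, PET coefficient 0.65,
soil 150 mm, stress threshold 0.5, t_ref_growth 10 °C, 150 weed seeds per
g shoot biomass (chosen so that a 10-percentage-point yield-loss step,
~100 g m⁻² of weed biomass, maps to roughly 15,000 extra seeds m⁻²).

## Synthetic weather

The generator produces the statistical structure the analysis needs, not
any observed record: a seasonal temperature sinusoid (annual mean 9.8 °C,
half-amplitude 6.5 °C, minimum mid-January) with AR(1) anomalies
(ρ = 0.7, sd 2 °C) and a ±4 °C diurnal half-range; a clear-sky radiation
sinusoid (13 ± 11 MJ m⁻² d⁻¹) damped by a daily uniform cloudiness factor
0.35–1.0 and floored at 0.5 MJ; rainfall from a two-state Markov chain
(p(wet|wet) = 0.6, p(wet|dry) = 0.3) with gamma amounts (shape 0.8, mean
4 mm). These are plausible values for a lowland site at 51.8 °N
(≈ 500 mm rain and ≈ 3100 dd over a September–July season). "Years" are
independent seeds, mirroring the assumption that seasons are temporally
independent; cold/warm presets shift the annual mean by ∓1.5 °C.

What the generator does *not* emulate: real inter-variable correlations
(cold clear spells, warm fronts with rain), serial correlation in
radiation and rainfall beyond the wet/dry chain, trends, and site
topography. Passing the directional checks under these conditions shows
the model's comparative statics are robust to realistic between-year
variability — it does not validate absolute magnitudes against any field
season.

## The in-silico experiments

* **Density × date grid** — 49 combinations (100–400 plants m⁻² in steps
  of 50; 15 September–14 November in steps of 10 days), one run per
  weather year, fixed weed density 80 m⁻² and emergence lags (crop 10 d,
  weed 7 d).
* **Cultivar battery** — Duxford vs KWS Santiago over 100–600 plants m⁻²
  and the two contrast dates (20 September, 20 October).
* **2×2×2 factorial** — cultivar × density (150/300) × date (20 Sep /
  20 Oct) across ten replicate years, analysed by a main-effects ANOVA
  with explicit sums of squares (residual df = 76 for the 80-run design);
  an optional balanced two-way-interaction decomposition is provided. The
  implementation is checked against an independent general-linear-model
  fit to 1e-8.
* **Summaries** — group means with SE = sd/√n; Pearson correlation of
  yield loss with weed biomass; rectangular-hyperbola fits
  `yl = A/(1 + B·d)` (scipy least squares, B ≥ 0, exact recovery on
  noiseless curves to 1e-6).
* **Equivalence solvers** — the density (or date) at which one cultivar
  matches a reference cultivar's mean loss: both density responses are
  smoothed by the hyperbola before inverting (robust at the 50-plant grid
  resolution); date responses are interpolated linearly in days and must
  be monotone. Solutions outside the simulated range are returned with an
  `extrapolated` flag rather than refused.

Problem sizes were chosen to keep the full pipeline (≈ 1,700 paired
season runs) under a minute on one CPU; a single season takes a few
milliseconds.

## Numerical and degenerate-input choices

* Determinism: no randomness outside the weather generator; identical
  inputs give bit-identical seasons.
* The competition switch latches: once total GAI reaches 0.75 the stand
  stays in the competition regime even when senescence later pulls GAI
  below the threshold. Growth is not clipped on the crossing day —
  clipping supply-limited growth would discard real assimilate and bias
  paired runs in opposite directions.
* Weed-free pairs short-circuit: with weed density 0 the weedy run *is*
  the control and the loss is exactly 0, not a rounding difference.
* A stand reporting green area with zero height, inverted temperatures,
  date gaps and negative rainfall are rejected with errors naming the
  offending quantity and row; a weather series ending before crop
  maturity raises an error naming the date reached.
* A crop that flowers before canopy closure continues to assimilate
  through its own canopy while relocation and senescence run, so very
  sparse or very late stands produce small but meaningful yields.

## Known limitations

* Below-ground competition is only implicit (shared water bucket; root
  pools do not compete for space or nutrients); nitrogen is absent.
* One weed cohort; no density-dependent establishment, no reduced weed
  emergence at late sowing — delayed-sowing benefits are therefore
  attributable purely to the temperature mechanism.
* Uniform vertical leaf-area profiles and a single extinction coefficient
  per species; no leaf-angle or direct/diffuse treatment.
* Vernalisation and photoperiod sensitivity of wheat development are not
  modelled; anthesis timing rests on the phyllochron and final leaf
  number.
* The weed parameter set is a stand-in; absolute yield-loss magnitudes
  should be read as model-internal, while the comparative results
  (density, date, cultivar, weather orderings) are the intended outputs.
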