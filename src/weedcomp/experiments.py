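"""In-silico factorial experiments on the season simulator.

The questions of interest — how much does each cultural lever (sowing
density, sowing date, cultivar choice) suppress the weed, and do the
levers combine additively across variable weather years — are answered by
running the season model over a factorial grid with replicate weather
years, then summarising:

* group means ± standard errors,
* a balanced factorial ANOVA (explicit sums of squares, years as
  replicates),
* rectangular-hyperbola fits of yield loss against crop density
  (diminishing returns),
* *equivalence* solvers: the density (or sowing date) at which one
  cultivar matches a reference cultivar's yield loss, and
* the correlation between percentage yield loss and weed biomass.
"""

from __future__ import annotations

import datetime as _dt
import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .canopy import CultivarTraits
from .physiology import ModelConstants
from .simulation import SeasonError, SimulationConfig, run_season
from .weather import WeatherSeries

__all__ = [
    "FactorialGrid",
    "RESULTS_COLUMNS",
    "run_factorial",
    "summarize",
    "anova_factorial",
    "fit_hyperbola",
    "HyperbolaFit",
    "EquivalenceResult",
    "equivalent_density",
    "equivalent_date",
    "loss_biomass_correlation",
]

RESULTS_COLUMNS = [
    "year", "cultivar", "density", "sowing_date", "yield_loss",
    "weed_biomass", "weedfree_yield", "seed_return",
    "season_mean_temp", "accumulated_tt",
]


@dataclass(frozen=True)
class FactorialGrid:
    """A density × sowing-date × cultivar grid run over replicate years.

    ``weather_set`` maps a year label to a :class:`WeatherSeries`; every
    series must cover every sowing date through crop maturity.  Weed
    density and emergence lags are held fixed across the grid.
    """

    densities: Sequence[float]
    sowing_dates: Sequence[_dt.date]
    cultivars: Sequence[CultivarTraits]
    weather_set: dict[str, WeatherSeries] | dict[int, WeatherSeries]
    weed_traits: CultivarTraits = None  # type: ignore[assignment]
    weed_density: float = 80.0
    crop_emergence_lag: int = 10
    weed_emergence_lag: int = 7
    constants: ModelConstants = field(default_factory=ModelConstants)
    latitude: float = 51.8

    def __post_init__(self) -> None:
        if not (self.densities and self.sowing_dates and self.cultivars and self.weather_set):
            raise ValueError("grid factors and weather set must be non-empty")
        if any(d <= 0 for d in self.densities):
            raise ValueError("crop densities must be positive")
        if self.weed_traits is None:
            raise ValueError("weed_traits is required")

    @property
    def n_cells(self) -> int:
        return len(self.densities) * len(self.sowing_dates) * len(self.cultivars)


def run_factorial(grid: FactorialGrid) -> pd.DataFrame:
    """Run one season per grid cell × weather year.

    Returns the long-format results table (one row per cell × year, columns
    :data:`RESULTS_COLUMNS`) in deterministic order.  Errors from
    individual seasons are re-raised with the cell coordinates attached.
    """
    rows = []
    for cult, density, date in itertools.product(
        grid.cultivars, grid.densities, grid.sowing_dates
    ):
        for year, weather in grid.weather_set.items():
            config = SimulationConfig(
                sowing_date=date,
                crop_traits=cult,
                weed_traits=grid.weed_traits,
                crop_density=density,
                weed_density=grid.weed_density,
                crop_emergence_lag=grid.crop_emergence_lag,
                weed_emergence_lag=grid.weed_emergence_lag,
                constants=grid.constants,
                latitude=grid.latitude,
            )
            try:
                res = run_season(config, weather)
            except SeasonError as exc:
                raise SeasonError(
                    f"cell (cultivar={cult.name}, density={density}, "
                    f"date={date}, year={year}): {exc}"
                ) from exc
            rows.append({
                "year": year,
                "cultivar": cult.name,
                "density": density,
                "sowing_date": date,
                "yield_loss": res.yield_loss,
                "weed_biomass": res.weed_shoot_biomass,
                "weedfree_yield": res.weedfree_yield,
                "seed_return": res.weed_seed_return,
                "season_mean_temp": res.season_mean_temp,
                "accumulated_tt": res.accumulated_tt,
            })
    return pd.DataFrame(rows, columns=RESULTS_COLUMNS)


def summarize(table: pd.DataFrame, group_by: Sequence[str], response: str) -> pd.DataFrame:
    """Mean and standard error (sd/√n) of ``response`` per group."""
    for col in list(group_by) + [response]:
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in results table")
    if len(table) == 0:
        raise ValueError("empty results table")
    grouped = table.groupby(list(group_by))[response]
    out = grouped.agg(mean="mean", n="count", sd=lambda s: s.std(ddof=1))
    out["sd"] = out["sd"].fillna(0.0)
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.reset_index()[list(group_by) + ["mean", "se", "n"]]


def anova_factorial(
    table: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    interactions: bool = False,
) -> pd.DataFrame:
    """Balanced factorial ANOVA by explicit sums of squares.

    Main effects only by default (each factor's SS from its level means
    about the grand mean); optionally all two-way interactions for a
    balanced complete design.  Residual df = n − 1 − Σ model df.  Requires
    a balanced complete factorial (equal cell counts), since main-effects
    sums of squares are otherwise order-dependent.

    Returns a tidy table with columns effect, df, ss, ms, F, p (the
    residual row carries NaN F and p).
    """
    factors = list(factors)
    if not factors:
        raise ValueError("at least one factor required")
    for col in factors + [response]:
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in results table")
    counts = table.groupby(factors).size()
    full = np.prod([table[f].nunique() for f in factors])
    if len(counts) != full or counts.nunique() != 1:
        raise ValueError("unbalanced or incomplete factorial; explicit SS would be order-dependent")
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")

    y = table[response].to_numpy(dtype=float)
    n = len(y)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    effects: list[tuple[str, int, float]] = []
    main_means = {}
    for f in factors:
        means = table.groupby(f)[response].mean()
        counts_f = table.groupby(f).size()
        ss = float((counts_f * (means - grand) ** 2).sum())
        effects.append((f, len(means) - 1, ss))
        main_means[f] = means

    if interactions:
        for f1, f2 in itertools.combinations(factors, 2):
            cell = table.groupby([f1, f2])[response].mean()
            cnt = table.groupby([f1, f2]).size()
            ss = 0.0
            for (l1, l2), m in cell.items():
                dev = m - main_means[f1][l1] - main_means[f2][l2] + grand
                ss += cnt[(l1, l2)] * dev ** 2
            df = (table[f1].nunique() - 1) * (table[f2].nunique() - 1)
            effects.append((f"{f1}:{f2}", df, float(ss)))

    model_df = sum(df for _, df, _ in effects)
    ss_model = sum(ss for _, _, ss in effects)
    df_res = n - 1 - model_df
    ss_res = ss_total - ss_model
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_res = ss_res / df_res

    rows = []
    for name, df, ss in effects:
        ms = ss / df
        if ms_res > 0:
            fval = ms / ms_res
            p = float(stats.f.sf(fval, df, df_res))
        else:
            fval, p = float("nan"), float("nan")
        rows.append({"effect": name, "df": df, "ss": ss, "ms": ms, "F": fval, "p": p})
    rows.append({"effect": "residual", "df": df_res, "ss": ss_res, "ms": ms_res,
                 "F": float("nan"), "p": float("nan")})
    return pd.DataFrame(rows, columns=["effect", "df", "ss", "ms", "F", "p"])


@dataclass(frozen=True)
class HyperbolaFit:
    """Least-squares fit of the diminishing-returns curve yl(d) = A/(1+B·d)."""

    a: float
    b: float
    residual_ss: float

    def __call__(self, density):
        return self.a / (1.0 + self.b * np.asarray(density, dtype=float))

    def inverse(self, loss: float) -> float:
        """Density at which the fitted curve predicts ``loss`` (requires B > 0)."""
        if self.b <= 0:
            raise ValueError("inverse undefined for a flat fit (B <= 0)")
        if loss <= 0 or loss > self.a:
            raise ValueError(f"loss {loss} outside the curve's range (0, {self.a}]")
        return (self.a / loss - 1.0) / self.b


def fit_hyperbola(densities: Sequence[float], yield_losses: Sequence[float]) -> HyperbolaFit:
    """Fit the rectangular hyperbola yl(d) = A / (1 + B·d), B ≥ 0.

    Captures the principle of diminishing returns: each added crop plant
    suppresses the weed by less than the one before.  Raises on
    non-convergence with fit diagnostics.
    """
    d = np.asarray(densities, dtype=float)
    yl = np.asarray(yield_losses, dtype=float)
    if len(np.unique(d)) < 3:
        raise ValueError("need at least 3 distinct densities")
    if np.any(yl <= 0):
        raise ValueError("yield losses must be positive for the hyperbola fit")
    a0 = float(yl.max())
    b0 = 1.0 / float(d.mean())
    try:
        popt, _ = optimize.curve_fit(
            lambda x, a, b: a / (1.0 + b * x), d, yl,
            p0=[a0, b0], bounds=([1e-12, 0.0], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - depends on data pathology
        raise RuntimeError(f"hyperbola fit failed to converge (p0=({a0}, {b0})): {exc}") from exc
    resid = yl - popt[0] / (1.0 + popt[1] * d)
    return HyperbolaFit(a=float(popt[0]), b=float(popt[1]), residual_ss=float(resid @ resid))


@dataclass(frozen=True)
class EquivalenceResult:
    """A solved equivalence point on the density or date axis."""

    value: float  # plants m⁻², or days offset from the first simulated date
    date: Optional[_dt.date]  # populated on the date axis
    reference_loss: float  # % yield loss being matched
    extrapolated: bool


def _mean_loss_curve(table: pd.DataFrame, cultivar: str, axis: str) -> pd.DataFrame:
    sub = table[table["cultivar"] == cultivar]
    if len(sub) == 0:
        raise ValueError(f"cultivar {cultivar!r} not in table")
    return summarize(sub, [axis], "yield_loss")


def equivalent_density(
    table: pd.DataFrame,
    reference: tuple[str, float],
    other_cultivar: str,
) -> EquivalenceResult:
    """Density at which ``other_cultivar`` matches the reference cultivar's
    mean yield loss at its reference density.

    Both density–loss responses are smoothed with a rectangular-hyperbola
    fit, the reference loss is read off the reference cultivar's fitted
    curve, and the other cultivar's curve is inverted.  A solution beyond
    the simulated density range is flagged ``extrapolated``.
    """
    ref_cult, ref_density = reference
    ref_curve = _mean_loss_curve(table, ref_cult, "density")
    oth_curve = _mean_loss_curve(table, other_cultivar, "density")
    ref_fit = fit_hyperbola(ref_curve["density"], ref_curve["mean"])
    oth_fit = fit_hyperbola(oth_curve["density"], oth_curve["mean"])
    if oth_fit.b <= 0:
        raise ValueError("other cultivar's density response is not decreasing")
    target = float(ref_fit(ref_density))
    density = oth_fit.inverse(target)
    lo, hi = float(oth_curve["density"].min()), float(oth_curve["density"].max())
    return EquivalenceResult(
        value=float(density), date=None, reference_loss=target,
        extrapolated=not lo <= density <= hi,
    )


def equivalent_date(
    table: pd.DataFrame,
    reference: tuple[str, _dt.date],
    other_cultivar: str,
) -> EquivalenceResult:
    """Sowing date at which ``other_cultivar`` matches the reference
    cultivar's mean yield loss at its reference date.

    Mean losses are interpolated linearly in days along each cultivar's
    date response, which must be monotone decreasing (later sowing, less
    loss).  A crossing outside the simulated window is flagged
    ``extrapolated`` and solved by linear extension of the boundary
    segment.
    """
    ref_cult, ref_date = reference
    ref_curve = _mean_loss_curve(table, ref_cult, "sowing_date").sort_values("sowing_date")
    oth_curve = _mean_loss_curve(table, other_cultivar, "sowing_date").sort_values("sowing_date")
    origin = min(ref_curve["sowing_date"].min(), oth_curve["sowing_date"].min())
    ref_x = np.array([(d - origin).days for d in ref_curve["sowing_date"]], dtype=float)
    oth_x = np.array([(d - origin).days for d in oth_curve["sowing_date"]], dtype=float)
    ref_y = ref_curve["mean"].to_numpy(dtype=float)
    oth_y = oth_curve["mean"].to_numpy(dtype=float)
    for name, y in (("reference", ref_y), ("other", oth_y)):
        if not np.all(np.diff(y) < 0):
            raise ValueError(f"{name} cultivar's date response is not monotone decreasing")
    target = float(np.interp((ref_date - origin).days, ref_x, ref_y))
    # invert the other cultivar's decreasing curve (np.interp needs ascending x)
    extrapolated = not (oth_y.min() <= target <= oth_y.max())
    if extrapolated:
        # extend the boundary segment linearly
        if target > oth_y.max():
            slope = (oth_y[1] - oth_y[0]) / (oth_x[1] - oth_x[0])
            days = oth_x[0] + (target - oth_y[0]) / slope
        else:
            slope = (oth_y[-1] - oth_y[-2]) / (oth_x[-1] - oth_x[-2])
            days = oth_x[-1] + (target - oth_y[-1]) / slope
    else:
        days = float(np.interp(target, oth_y[::-1], oth_x[::-1]))
    return EquivalenceResult(
        value=float(days),
        date=origin + _dt.timedelta(days=round(float(days))),
        reference_loss=target,
        extrapolated=extrapolated,
    )


def loss_biomass_correlation(table: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of yield loss vs weed biomass."""
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    x = table["yield_loss"].to_numpy(dtype=float)
    y = table["weed_biomass"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in yield_loss or weed_biomass")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
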