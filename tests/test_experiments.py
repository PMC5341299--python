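import datetime as dt
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from weedcomp.experiments import (
    FactorialGrid,
    anova_factorial,
    equivalent_date,
    equivalent_density,
    fit_hyperbola,
    loss_biomass_correlation,
    run_factorial,
    summarize,
)


def synthetic_table(losses_by_cell, years=1):
    """Build a minimal results table from {(cultivar, density, date): loss}."""
    rows = []
    for (cult, dens, date), loss in losses_by_cell.items():
        for y in range(years):
            rows.append({
                "year": y, "cultivar": cult, "density": dens, "sowing_date": date,
                "yield_loss": loss, "weed_biomass": 10.0 * loss,
                "weedfree_yield": 8.0, "seed_return": 1500.0 * loss,
                "season_mean_temp": 9.0, "accumulated_tt": 2500.0,
            })
    return pd.DataFrame(rows)


class TestRunFactorial:
    def test_single_cell_single_year(self, consort, blackgrass, warm_weather):
        grid = FactorialGrid(
            densities=[250.0], sowing_dates=[dt.date(2020, 3, 1)],
            cultivars=[consort], weather_set={"y1": warm_weather},
            weed_traits=blackgrass,
        )
        table = run_factorial(grid)
        assert len(table) == 1
        assert grid.n_cells == 1

    def test_cells_times_years_rows_and_determinism(self, consort, duxford,
                                                    blackgrass, warm_weather):
        grid = FactorialGrid(
            densities=[150.0, 300.0],
            sowing_dates=[dt.date(2020, 3, 1), dt.date(2020, 3, 21)],
            cultivars=[consort, duxford],
            weather_set={"y1": warm_weather, "y2": warm_weather},
            weed_traits=blackgrass,
        )
        table = run_factorial(grid)
        assert len(table) == grid.n_cells * 2 == 16
        again = run_factorial(grid)
        pd.testing.assert_frame_equal(table, again)

    def test_49_combination_grid_shape(self):
        densities = list(range(100, 401, 50))
        dates = [dt.date(2005, 9, 15) + dt.timedelta(days=10 * i) for i in range(7)]
        assert len(densities) * len(dates) == 49
        assert dates[-1] == dt.date(2005, 11, 14)

    def test_season_error_carries_cell_coordinates(self, consort, blackgrass,
                                                   autumn_weather):
        short = autumn_weather.slice(autumn_weather.start,
                                     autumn_weather.start + dt.timedelta(days=60))
        grid = FactorialGrid(
            densities=[250.0], sowing_dates=[dt.date(2005, 9, 20)],
            cultivars=[consort], weather_set={"y1": short}, weed_traits=blackgrass,
        )
        with pytest.raises(Exception, match="density=250"):
            run_factorial(grid)


class TestSummarize:
    def test_hand_computed_mean_and_se(self):
        table = synthetic_table({("A", 100.0, dt.date(2020, 1, 1)): 0.0})
        table = pd.concat([table] * 3, ignore_index=True)
        table["yield_loss"] = [2.0, 4.0, 6.0]
        out = summarize(table, ["cultivar"], "yield_loss")
        assert out.loc[0, "mean"] == pytest.approx(4.0)
        assert out.loc[0, "se"] == pytest.approx(2.0 / math.sqrt(3))

    def test_identical_values_zero_se(self):
        table = synthetic_table({("A", 100.0, dt.date(2020, 1, 1)): 5.0}, years=4)
        out = summarize(table, ["cultivar"], "yield_loss")
        assert out.loc[0, "se"] == 0.0

    def test_balanced_grand_mean_identity(self):
        cells = {("A", d, dt.date(2020, 1, 1)): loss
                 for d, loss in [(100.0, 10.0), (200.0, 6.0), (300.0, 2.0)]}
        table = synthetic_table(cells, years=5)
        groups = summarize(table, ["density"], "yield_loss")
        assert groups["mean"].mean() == pytest.approx(table["yield_loss"].mean())

    def test_unknown_column_rejected(self):
        table = synthetic_table({("A", 100.0, dt.date(2020, 1, 1)): 1.0})
        with pytest.raises(KeyError):
            summarize(table, ["nonsense"], "yield_loss")


class TestAnova:
    @staticmethod
    def random_balanced_table(seed=0, reps=10):
        rng = np.random.default_rng(seed)
        rows = []
        for cult, dens, date in itertools.product(["A", "B"], [150, 300], ["s1", "s2"]):
            base = (cult == "B") * 5 + (dens == 150) * 3 + (date == "s1") * 2
            for r in range(reps):
                rows.append({"cultivar": cult, "density": dens, "sowing_date": date,
                             "yield_loss": base + rng.normal(0, 1.5)})
        return pd.DataFrame(rows)

    def test_2x2x2_by_10_reps_residual_df_76(self):
        table = self.random_balanced_table()
        out = anova_factorial(table, "yield_loss",
                              ["cultivar", "density", "sowing_date"])
        resid = out[out.effect == "residual"].iloc[0]
        assert resid.df == 76
        assert set(out.df[:-1]) == {1}

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        table = self.random_balanced_table(seed=3)
        ours = anova_factorial(table, "yield_loss",
                               ["cultivar", "density", "sowing_date"])
        fit = smf.ols("yield_loss ~ C(cultivar) + C(density) + C(sowing_date)",
                      data=table).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        for effect, ref_name in [("cultivar", "C(cultivar)"),
                                 ("density", "C(density)"),
                                 ("sowing_date", "C(sowing_date)")]:
            row = ours[ours.effect == effect].iloc[0]
            assert row.ss == pytest.approx(ref.loc[ref_name, "sum_sq"], rel=1e-8)
            assert row.F == pytest.approx(ref.loc[ref_name, "F"], rel=1e-8)
            assert row.p == pytest.approx(ref.loc[ref_name, "PR(>F)"], rel=1e-6, abs=1e-12)
        ours_res = ours[ours.effect == "residual"].iloc[0]
        assert ours_res.ss == pytest.approx(ref.loc["Residual", "sum_sq"], rel=1e-8)

    def test_interactions_match_statsmodels(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        table = self.random_balanced_table(seed=7)
        ours = anova_factorial(table, "yield_loss", ["cultivar", "density"],
                               interactions=True)
        fit = smf.ols("yield_loss ~ C(cultivar) * C(density)", data=table).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        row = ours[ours.effect == "cultivar:density"].iloc[0]
        assert row.ss == pytest.approx(ref.loc["C(cultivar):C(density)", "sum_sq"],
                                       rel=1e-8)

    def test_ss_decomposition(self):
        table = self.random_balanced_table(seed=11)
        out = anova_factorial(table, "yield_loss",
                              ["cultivar", "density", "sowing_date"])
        y = table["yield_loss"].to_numpy()
        ss_total = ((y - y.mean()) ** 2).sum()
        assert out.ss.sum() == pytest.approx(ss_total, rel=1e-8)

    def test_constant_response_flagged(self):
        table = self.random_balanced_table()
        table["yield_loss"] = 7.0
        out = anova_factorial(table, "yield_loss", ["cultivar", "density"])
        assert out.ss.abs().max() == pytest.approx(0.0, abs=1e-18)
        assert np.isnan(out[out.effect == "cultivar"].F.iloc[0])

    def test_unbalanced_table_rejected(self):
        table = self.random_balanced_table().iloc[:-1]
        with pytest.raises(ValueError, match="balanced|unbalanced"):
            anova_factorial(table, "yield_loss", ["cultivar", "density"])


class TestHyperbola:
    def test_exact_parameter_recovery(self):
        d = np.array([100, 150, 200, 300, 450, 600], dtype=float)
        yl = 50.0 / (1.0 + 0.01 * d)
        fit = fit_hyperbola(d, yl)
        assert fit.a == pytest.approx(50.0, rel=1e-6)
        assert fit.b == pytest.approx(0.01, rel=1e-6)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-12)

    def test_constant_losses_flat_fit(self):
        d = np.array([100, 200, 300, 400], dtype=float)
        fit = fit_hyperbola(d, np.full(4, 12.0))
        assert fit.b == pytest.approx(0.0, abs=1e-6)
        assert fit.a == pytest.approx(12.0, rel=1e-4)

    def test_fitted_curve_strictly_decreasing_when_b_positive(self):
        d = np.array([100, 200, 300, 500], dtype=float)
        fit = fit_hyperbola(d, 40.0 / (1.0 + 0.008 * d))
        dense = np.linspace(50, 700, 100)
        vals = fit(dense)
        assert np.all(np.diff(vals) < 0)

    def test_too_few_densities_rejected(self):
        with pytest.raises(ValueError):
            fit_hyperbola([100, 100, 100], [5.0, 5.0, 5.0])


class TestEquivalence:
    @staticmethod
    def hyperbola_table():
        dates = dt.date(2020, 9, 20)
        cells = {}
        for d in (100, 150, 200, 300, 450, 600):
            cells[("strong", float(d), dates)] = 30.0 / (1.0 + 0.01 * d)
            cells[("weak", float(d), dates)] = 60.0 / (1.0 + 0.01 * d)
        return synthetic_table(cells)

    def test_self_equivalence_identity(self):
        table = self.hyperbola_table()
        res = equivalent_density(table, ("weak", 150.0), "weak")
        assert res.value == pytest.approx(150.0, rel=1e-6)
        assert not res.extrapolated

    def test_constructed_crossing_recovered(self):
        # weak needs 60/(1+0.01 d) = 30/(1+1.5) = 12 -> d = 400
        table = self.hyperbola_table()
        res = equivalent_density(table, ("strong", 150.0), "weak")
        assert res.value == pytest.approx(400.0, rel=1e-6)
        assert not res.extrapolated

    def test_out_of_range_flagged_extrapolated(self):
        dates = dt.date(2020, 9, 20)
        cells = {}
        for d in (100, 150, 200, 300):
            cells[("strong", float(d), dates)] = 10.0 / (1.0 + 0.02 * d)
            cells[("weak", float(d), dates)] = 80.0 / (1.0 + 0.002 * d)
        res = equivalent_density(synthetic_table(cells), ("strong", 150.0), "weak")
        assert res.extrapolated
        assert res.value > 300.0

    @staticmethod
    def date_table():
        base = dt.date(2020, 9, 15)
        cells = {}
        for i in range(7):
            date = base + dt.timedelta(days=10 * i)
            cells[("strong", 150.0, date)] = 20.0 - 2.0 * i
            cells[("weak", 150.0, date)] = 40.0 - 4.0 * i
        return synthetic_table(cells)

    def test_date_self_equivalence(self):
        res = equivalent_date(self.date_table(), ("weak", dt.date(2020, 9, 25)), "weak")
        assert res.date == dt.date(2020, 9, 25)

    def test_date_crossing_linear_interpolation(self):
        # strong at 25 Sep: 20 - 2*(10/10) = 18; weak hits 18 at
        # 40 - 4*(days/10) = 18 -> days = 55 from 15 Sep -> 9 Nov
        res = equivalent_date(self.date_table(), ("strong", dt.date(2020, 9, 25)), "weak")
        assert res.value == pytest.approx(55.0, abs=1e-9)
        assert res.date == dt.date(2020, 11, 9)
        assert not res.extrapolated

    def test_date_crossing_beyond_window_flagged(self):
        # shallow weak response: crossing lies past the last simulated date
        base = dt.date(2020, 9, 15)
        cells = {}
        for i in range(7):
            date = base + dt.timedelta(days=10 * i)
            cells[("strong", 150.0, date)] = 20.0 - 2.0 * i
            cells[("weak", 150.0, date)] = 40.0 - 1.0 * i
        res = equivalent_date(synthetic_table(cells), ("strong", dt.date(2020, 9, 25)),
                              "weak")
        assert res.extrapolated
        assert res.value > 60.0

    def test_non_monotone_date_response_rejected(self):
        table = self.date_table()
        table.loc[table.index[-1], "yield_loss"] = 99.0
        with pytest.raises(ValueError, match="monotone"):
            equivalent_date(table, ("strong", dt.date(2020, 9, 25)), "weak")


class TestCorrelation:
    def test_exact_line_r_one(self):
        table = synthetic_table(
            {("A", float(d), dt.date(2020, 1, 1)): float(v)
             for d, v in [(100, 1), (200, 2), (300, 3), (400, 4)]}
        )
        r, p = loss_biomass_correlation(table)
        assert r == pytest.approx(1.0)

    def test_anti_line_r_minus_one(self):
        table = synthetic_table(
            {("A", float(d), dt.date(2020, 1, 1)): float(v)
             for d, v in [(100, 1), (200, 2), (300, 3)]}
        )
        table["weed_biomass"] = -table["weed_biomass"]
        r, _ = loss_biomass_correlation(table)
        assert r == pytest.approx(-1.0)

    def test_matches_hand_computation_on_five_rows(self):
        x = np.array([3.0, 7.0, 1.0, 9.0, 5.0])
        y = np.array([210.0, 640.0, 150.0, 780.0, 420.0])
        table = synthetic_table(
            {("A", float(i), dt.date(2020, 1, 1)): 0.0 for i in range(5)}
        )
        table["yield_loss"] = x
        table["weed_biomass"] = y
        r, _ = loss_biomass_correlation(table)
        xm, ym = x - x.mean(), y - y.mean()
        expected = (xm @ ym) / math.sqrt((xm @ xm) * (ym @ ym))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        table = synthetic_table({("A", 100.0, dt.date(2020, 1, 1)): 5.0}, years=5)
        with pytest.raises(ValueError, match="variance"):
            loss_biomass_correlation(table)
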