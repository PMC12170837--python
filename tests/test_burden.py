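"""Burden formulas: worked arithmetic, bound construction, projections."""

import numpy as np
import pandas as pd
import pytest

from heatosa.attribution import Climatology, ExcessSeries, climatology_1950_1990
from heatosa.burden import (
    BurdenParams,
    CountryParams,
    adjusted_labor_force,
    compute_burden,
    daly,
    labor_loss,
    productivity_days,
    project_scenario,
    uncertainty_bounds,
    wellbeing_cost,
    years_lived_disability,
    years_of_life_lost,
)
from heatosa.curves import ExposureResponseCurve
from heatosa.synthetic import DailySeries


@pytest.fixture()
def cp():
    return CountryParams(
        country="T",
        osa_prevalence=0.2,
        adult_population=1e7,
        mva_death_rate=2e-7,
        residual_life_expectancy=30.0,
        labor_force=1e6,
        part_time_share=0.2,
        gdp_per_capita=50_000.0,
        gdp_per_capita_employed=73_000.0,
    )


@pytest.fixture()
def bp():
    return BurdenParams()


def flat_excess(mean, year=2023):
    return ExcessSeries(year, np.full(365, mean))


class TestYLL:
    def test_zero_excess(self, cp, bp):
        assert years_of_life_lost(flat_excess(0.0), cp, bp) == 0.0

    def test_lower_bound_is_half_the_mean(self, cp, bp):
        ex = flat_excess(0.03)
        assert years_of_life_lost(ex, cp, bp, "lower") == pytest.approx(
            0.5 * years_of_life_lost(ex, cp, bp, "mean")
        )

    def test_worked_arithmetic(self, cp, bp):
        ex = flat_excess(0.05)
        assert years_of_life_lost(ex, cp, bp) == pytest.approx(0.6)


class TestYLD:
    def test_zero_disability_weight(self, cp):
        bp0 = BurdenParams(disability_weight=(0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            # DW mean of zero makes the ratio bounds undefined
            uncertainty_bounds(1.0, bp0.disability_weight)
        assert years_lived_disability(flat_excess(0.1), cp, bp0) == 0.0

    def test_lower_bound_ratio_is_0625(self, cp, bp):
        ex = flat_excess(0.04)
        assert years_lived_disability(ex, cp, bp, "lower") == pytest.approx(
            0.625 * years_lived_disability(ex, cp, bp, "mean")
        )


class TestDalyAndCost:
    def test_daly_is_exact_sum(self):
        assert daly(58_341.0, 1_024.0) == 59_365.0
        assert daly(0.0, 0.0) == 0.0

    def test_daly_additive_across_countries(self, cp, bp):
        e1, e2 = flat_excess(0.02), flat_excess(0.07)
        total = daly(
            years_of_life_lost(e1, cp, bp), years_lived_disability(e1, cp, bp)
        ) + daly(
            years_of_life_lost(e2, cp, bp), years_lived_disability(e2, cp, bp)
        )
        combined = daly(
            years_of_life_lost(e1, cp, bp) + years_of_life_lost(e2, cp, bp),
            years_lived_disability(e1, cp, bp) + years_lived_disability(e2, cp, bp),
        )
        assert total == pytest.approx(combined)

    def test_wellbeing_cost_arithmetic_and_ratio(self, bp):
        assert wellbeing_cost(1000.0, 50_000.0, "mean", bp) == pytest.approx(1e8)
        assert wellbeing_cost(1000.0, 50_000.0, "lower", bp) == pytest.approx(
            0.5 * wellbeing_cost(1000.0, 50_000.0, "mean", bp)
        )


class TestProductivity:
    def test_part_time_adjustment(self):
        assert adjusted_labor_force(1000.0, 0.0) == 1000.0
        assert adjusted_labor_force(1000.0, 1.0) == 500.0
        assert adjusted_labor_force(1000.0, 0.2) == 900.0

    def test_zero_rates_give_zero_days(self, cp):
        bp0 = BurdenParams(presenteeism_rate=0.0, absenteeism_rate=0.0)
        assert productivity_days(flat_excess(0.1), cp, bp0) == (0.0, 0.0)

    def test_ratio_is_exactly_68_to_21(self, cp, bp):
        pres, absd = productivity_days(flat_excess(0.033), cp, bp)
        assert pres / absd == pytest.approx(6.8 / 2.1, rel=1e-12)

    def test_worked_arithmetic(self, cp, bp):
        # sum of excess = 10, p0 0.25, adjusted LF 1e6
        ex = ExcessSeries(2023, np.full(365, 10.0 / 365.0))
        pres, _ = productivity_days(ex, cp, bp, p0=0.25, lf_adjusted=1e6)
        assert pres == pytest.approx(235 / 365 * 10 * 0.25 * 1e6 * 0.068, rel=1e-9)

    def test_labor_loss(self):
        assert labor_loss(365.0, 0.0, 73_000.0) == pytest.approx(73_000.0)
        assert labor_loss(0.0, 0.0, 73_000.0) == 0.0
        with pytest.raises(ValueError):
            labor_loss(-1.0, 0.0, 73_000.0)


class TestUncertaintyBounds:
    def test_ratio_construction(self):
        lo, mid, hi = uncertainty_bounds(1024.0, (0.5, 1.0, 1.5))
        assert lo == 512.0 and mid == 1024.0 and hi == 1536.0

    def test_degenerate_triplet(self):
        assert uncertainty_bounds(7.0, (1.0, 1.0, 1.0)) == (7.0, 7.0, 7.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            uncertainty_bounds(1.0, (0.0, 0.0, 1.0))


class TestComputeBurden:
    def test_daly_decomposition_at_all_levels(self, cp, bp):
        res = compute_burden(flat_excess(0.05), cp, bp)
        for i in range(3):
            assert res.daly[i] == pytest.approx(res.yll[i] + res.yld[i])
        assert res.yll[0] <= res.yll[1] <= res.yll[2]
        assert res.labor_loss[0] <= res.labor_loss[1] <= res.labor_loss[2]

    def test_homogeneous_in_population(self, cp, bp):
        ex = flat_excess(0.05)
        base = compute_burden(ex, cp, bp)
        doubled = compute_burden(ex, cp, bp, apop=2 * cp.adult_population)
        for name in ("yll", "yld", "daly"):
            assert getattr(doubled, name)[1] == pytest.approx(
                2 * getattr(base, name)[1]
            )

    def test_curve_envelope_drives_productivity_bounds(self, cp, bp):
        levels = {
            "lower": flat_excess(0.02),
            "mean": flat_excess(0.05),
            "upper": flat_excess(0.09),
        }
        res = compute_burden(levels, cp, bp)
        assert res.presenteeism_days[0] < res.presenteeism_days[1] < res.presenteeism_days[2]
        # YLL bounds still come from the RR_MVA triplet at the mean curve
        assert res.yll[0] == pytest.approx(0.5 * res.yll[1])


def _const_series(values, start):
    dates = pd.date_range(start, periods=len(values), freq="D")
    return DailySeries("T", pd.DataFrame({"date": dates, "tmean": values}))


class TestProjection:
    def setup_method(self):
        grid = np.linspace(-10, 40, 101)
        self.curve = ExposureResponseCurve(
            grid=grid,
            log_rr=0.02 * (grid - 10.0),
            var=np.full(grid.size, 1e-4),
            reference=10.0,
        )
        self.clim = Climatology("T", np.full(365, 10.0))

    def test_scenario_identical_to_climatology_is_all_zero(self, cp, bp):
        n = (pd.Timestamp("2025-12-31") - pd.Timestamp("2024-01-01")).days + 1
        dates = pd.date_range("2024-01-01", periods=n, freq="D")
        vals = np.array(
            [self.clim.values[min(d.dayofyear, 365) - 1] for d in dates]
        )
        scen = _const_series(vals, "2024-01-01")
        traj = project_scenario(self.curve, scen, self.clim, cp, bp)
        assert traj.cumulative("daly") == pytest.approx(0.0, abs=1e-9)
        assert traj.cumulative("labor_loss") == pytest.approx(0.0, abs=1e-9)

    def test_uniform_warming_gives_nonnegative_burden(self, cp, bp):
        n = 365 * 2 + 1  # 2024 is a leap year
        scen = _const_series(np.full(n, 13.0), "2024-01-01")
        traj = project_scenario(self.curve, scen, self.clim, cp, bp)
        assert (traj.series("daly") >= 0).all()

    def test_sensitivity_mode_scales_by_prevalence_and_population(self, bp, cp):
        n = 365
        scen = _const_series(np.full(n, 14.0), "2054-01-01")
        cp2 = CountryParams(
            **{
                **{
                    f: getattr(cp, f)
                    for f in (
                        "country",
                        "osa_prevalence",
                        "adult_population",
                        "mva_death_rate",
                        "residual_life_expectancy",
                        "labor_force",
                        "part_time_share",
                        "gdp_per_capita",
                        "gdp_per_capita_employed",
                    )
                },
                "population_forecast": {2054: 1.2 * cp.adult_population},
            }
        )
        primary = project_scenario(self.curve, scen, self.clim, cp2, bp, mode="primary")
        sens = project_scenario(self.curve, scen, self.clim, cp2, bp, mode="sensitivity")
        # beyond 2050 the prevalence ramp is a flat 1.3x; population 1.2x
        assert sens.series("yld")[0] == pytest.approx(
            1.3 * 1.2 * primary.series("yld")[0]
        )
        # productivity scales with prevalence only (labor force held fixed)
        assert sens.series("presenteeism_days")[0] == pytest.approx(
            1.3 * primary.series("presenteeism_days")[0]
        )

    def test_missing_years_rejected(self, cp, bp):
        scen = _const_series(np.full(365, 14.0), "2030-01-01")
        with pytest.raises(ValueError):
            project_scenario(
                self.curve, scen, self.clim, cp, bp, years=[2030, 2031]
            )
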