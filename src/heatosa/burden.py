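"""Health and economic burden of warming-attributable OSA.

Converts excess-risk series into years of life lost (YLL, via the
OSA/motor-vehicle-accident mortality pathway), years lived with disability
(YLD), DALYs, a wellbeing cost (DALYs valued at multiples of GDP per
capita), presenteeism/absenteeism days and the resulting labor loss.

The formulas are implemented exactly in their published annual-mean form:

    YLL  = (1/365) sum_d [RR(T_d) - RR(Thist_d)] * p0 * APOP
                   * (MVA_death_rate * RR_MVA) * RLE
    YLD  = (1/365) sum_d [...] * p0 * APOP * DW * L
    DALY = YLL + YLD
    PRES = (NWD/365) sum_d [...] * p0 * LF_adj * PRES_rate   (ABS likewise)
    LL   = (PRES + ABS) * GDP_per_capita_employed / 365

Uncertainty: YLL bounds scale the MVA risk ratio through (0.5, 1.0, 1.5),
YLD bounds the disability weight through (0.05, 0.08, 0.11), the wellbeing
cost values a DALY at (1, 2, 3) x GDP per capita, and the productivity
outputs are evaluated at the exposure-response curve's 95% CI envelope.
All outputs are linear in the varied parameter, so bounds are exact ratios
of the mean — see :func:`uncertainty_bounds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .attribution import Climatology, ExcessSeries, daily_excess_risk
from .curves import ExposureResponseCurve
from .synthetic import DailySeries

__all__ = [
    "CountryParams",
    "BurdenParams",
    "BurdenResult",
    "ScenarioTrajectory",
    "years_of_life_lost",
    "years_lived_disability",
    "daly",
    "wellbeing_cost",
    "adjusted_labor_force",
    "productivity_days",
    "labor_loss",
    "uncertainty_bounds",
    "compute_burden",
    "project_scenario",
]

_LEVELS = ("lower", "mean", "upper")


def _level_index(level: str) -> int:
    try:
        return _LEVELS.index(level)
    except ValueError:
        raise ValueError(f"level must be one of {_LEVELS}") from None


@dataclass(frozen=True)
class CountryParams:
    """Per-country scalars feeding the burden formulas."""

    country: str
    osa_prevalence: float  # p0, fraction of adults with OSA
    adult_population: float  # APOP, persons (2023 estimate)
    mva_death_rate: float  # fatal motor-vehicle accidents per person per day
    residual_life_expectancy: float  # years lost per MVA death (RLE)
    labor_force: float  # persons
    part_time_share: float  # fraction of labor force working part-time
    gdp_per_capita: float  # USD
    gdp_per_capita_employed: float  # USD
    population_forecast: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("osa_prevalence", "part_time_share"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "adult_population",
            "mva_death_rate",
            "residual_life_expectancy",
            "labor_force",
            "gdp_per_capita",
            "gdp_per_capita_employed",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def synthetic_default(cls, country: str = "SYN") -> "CountryParams":
        """Plausible mid-size high-income country, for synthetic pipelines.

        Values are round numbers in the range of World Bank / UN / GBD
        figures for a western European country: ~53M adults, 25% OSA
        prevalence, road-death rate ~8.7 per 100k per year (expressed per
        person-day), 35 years of residual life per fatal accident.
        """
        return cls(
            country=country,
            osa_prevalence=0.25,
            adult_population=53e6,
            mva_death_rate=8.7e-5 / 365.0,
            residual_life_expectancy=35.0,
            labor_force=34e6,
            part_time_share=0.24,
            gdp_per_capita=49_000.0,
            gdp_per_capita_employed=95_000.0,
        )

    def population(self, year: int, use_forecast: bool = False) -> float:
        if use_forecast and self.population_forecast:
            years = sorted(self.population_forecast)
            if year in self.population_forecast:
                return float(self.population_forecast[year])
            # nearest-neighbour outside, linear inside
            if year <= years[0]:
                return float(self.population_forecast[years[0]])
            if year >= years[-1]:
                return float(self.population_forecast[years[-1]])
            return float(
                np.interp(year, years, [self.population_forecast[y] for y in years])
            )
        return self.adult_population


def _triplet(v: Sequence[float], name: str) -> tuple[float, float, float]:
    lo, mid, hi = (float(x) for x in v)
    if not lo <= mid <= hi:
        raise ValueError(f"{name} triplet must be ordered lower <= mean <= upper")
    return (lo, mid, hi)


@dataclass(frozen=True)
class BurdenParams:
    """Shared burden parameters with (lower, mean, upper) uncertainty sets."""

    rr_mva_osa: tuple[float, float, float] = (0.5, 1.0, 1.5)
    disability_weight: tuple[float, float, float] = (0.05, 0.08, 0.11)
    impairment_duration_days: float = 1.0
    daly_value_multiplier: tuple[float, float, float] = (1.0, 2.0, 3.0)
    working_days: float = 235.0  # NWD, full-time working days per year
    presenteeism_rate: float = 0.068
    absenteeism_rate: float = 0.021

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rr_mva_osa", _triplet(self.rr_mva_osa, "rr_mva_osa")
        )
        object.__setattr__(
            self,
            "disability_weight",
            _triplet(self.disability_weight, "disability_weight"),
        )
        object.__setattr__(
            self,
            "daly_value_multiplier",
            _triplet(self.daly_value_multiplier, "daly_value_multiplier"),
        )
        for name in ("presenteeism_rate", "absenteeism_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


# ---------------------------------------------------------------------------
# single-year quantities


def years_of_life_lost(
    excess: ExcessSeries,
    cp: CountryParams,
    bp: BurdenParams,
    level: str = "mean",
    p0: float | None = None,
    apop: float | None = None,
) -> float:
    """YLL from OSA-attributable fatal motor-vehicle accidents."""
    i = _level_index(level)
    p0 = cp.osa_prevalence if p0 is None else p0
    apop = cp.adult_population if apop is None else apop
    mva_osa_rate = cp.mva_death_rate * bp.rr_mva_osa[i]
    return excess.mean * p0 * apop * mva_osa_rate * cp.residual_life_expectancy


def years_lived_disability(
    excess: ExcessSeries,
    cp: CountryParams,
    bp: BurdenParams,
    level: str = "mean",
    p0: float | None = None,
    apop: float | None = None,
) -> float:
    """YLD from the extra person-days lived with OSA."""
    i = _level_index(level)
    p0 = cp.osa_prevalence if p0 is None else p0
    apop = cp.adult_population if apop is None else apop
    dw = bp.disability_weight[i]
    return excess.mean * p0 * apop * dw * bp.impairment_duration_days


def daly(yll: float, yld: float) -> float:
    """Disability-adjusted life years: YLL + YLD."""
    return yll + yld


def wellbeing_cost(
    daly_years: float, gdp_per_capita: float, level: str = "mean", bp: BurdenParams | None = None
) -> float:
    """Value the DALY loss at (1, 2, 3) x GDP per capita."""
    bp = bp or BurdenParams()
    return daly_years * bp.daly_value_multiplier[_level_index(level)] * gdp_per_capita


def adjusted_labor_force(lf: float, pt_share: float) -> float:
    """Down-weight part-time workers at half a full-time equivalent."""
    if not 0 <= pt_share <= 1:
        raise ValueError("part-time share must be in [0, 1]")
    return lf - lf * pt_share / 2.0


def productivity_days(
    excess: ExcessSeries,
    cp: CountryParams,
    bp: BurdenParams,
    p0: float | None = None,
    lf_adjusted: float | None = None,
) -> tuple[float, float]:
    """(presenteeism days, absenteeism days) for one year."""
    p0 = cp.osa_prevalence if p0 is None else p0
    if lf_adjusted is None:
        lf_adjusted = adjusted_labor_force(cp.labor_force, cp.part_time_share)
    base = bp.working_days / 365.0 * excess.total * p0 * lf_adjusted
    return base * bp.presenteeism_rate, base * bp.absenteeism_rate


def labor_loss(pres: float, abs_days: float, gdp_per_capita_employed: float) -> float:
    """Labor loss in USD: total lost days x GDP per capita employed / 365."""
    if pres < 0 or abs_days < 0:
        raise ValueError("day counts must be non-negative")
    return (pres + abs_days) * gdp_per_capita_employed / 365.0


def uncertainty_bounds(
    point_at_mean: float, triplet: Sequence[float]
) -> tuple[float, float, float]:
    """Bounds for a quantity linear in a (lower, mean, upper) parameter:
    scale the mean-level value by the parameter ratios."""
    lo, mid, hi = (float(v) for v in triplet)
    if mid == 0:
        raise ValueError("parameter mean must be non-zero")
    return (point_at_mean * lo / mid, point_at_mean, point_at_mean * hi / mid)


# ---------------------------------------------------------------------------
# yearly bundle and scenario projection


@dataclass
class BurdenResult:
    """All burden outputs for one country-year, each as (lower, mean, upper)."""

    year: int
    yll: tuple[float, float, float]
    yld: tuple[float, float, float]
    daly: tuple[float, float, float]
    wellbeing_cost: tuple[float, float, float]
    presenteeism_days: tuple[float, float, float]
    absenteeism_days: tuple[float, float, float]
    labor_loss: tuple[float, float, float]
    excess_person_days: float = 0.0

    def __post_init__(self) -> None:
        for lvl in range(3):
            if abs(self.daly[lvl] - (self.yll[lvl] + self.yld[lvl])) > 1e-6 * max(
                1.0, abs(self.daly[lvl])
            ):
                raise ValueError("DALY must equal YLL + YLD at every bound level")

    def rounded(self) -> dict:
        """Flat serialisation view: person-day/day/year counts rounded to
        the nearest integer, one key per quantity and bound level."""
        out = {"year": self.year}
        for name in ("yll", "yld", "daly", "presenteeism_days", "absenteeism_days"):
            for lvl, v in zip(_LEVELS, getattr(self, name)):
                out[f"{name}_{lvl}"] = int(round(v))
        for name in ("wellbeing_cost", "labor_loss"):
            for lvl, v in zip(_LEVELS, getattr(self, name)):
                out[f"{name}_{lvl}"] = float(v)
        out["excess_person_days"] = int(round(self.excess_person_days))
        return out


def compute_burden(
    excess_by_level: Mapping[str, ExcessSeries] | ExcessSeries,
    cp: CountryParams,
    bp: BurdenParams | None = None,
    p0: float | None = None,
    apop: float | None = None,
) -> BurdenResult:
    """Assemble every burden output for one country-year.

    ``excess_by_level`` is either a single mean-curve excess series, or a
    dict with 'lower'/'mean'/'upper' series from the curve's CI envelope —
    the latter drives the bounds of the productivity outputs.  YLL/YLD/
    wellbeing bounds always come from their parameter triplets, at the
    mean-curve excess.
    """
    bp = bp or BurdenParams()
    if isinstance(excess_by_level, ExcessSeries):
        excess_by_level = {lvl: excess_by_level for lvl in _LEVELS}
    mean_ex = excess_by_level["mean"]
    p0 = cp.osa_prevalence if p0 is None else p0
    apop_v = cp.adult_population if apop is None else apop

    yll = uncertainty_bounds(
        years_of_life_lost(mean_ex, cp, bp, "mean", p0=p0, apop=apop_v),
        bp.rr_mva_osa,
    )
    yld = uncertainty_bounds(
        years_lived_disability(mean_ex, cp, bp, "mean", p0=p0, apop=apop_v),
        bp.disability_weight,
    )
    dalys = tuple(daly(a, b) for a, b in zip(yll, yld))
    wb = tuple(
        wellbeing_cost(dalys[1], cp.gdp_per_capita, lvl, bp) for lvl in _LEVELS
    )

    lf_adj = adjusted_labor_force(cp.labor_force, cp.part_time_share)
    pres = []
    absd = []
    for lvl in _LEVELS:
        p, a = productivity_days(
            excess_by_level[lvl], cp, bp, p0=p0, lf_adjusted=lf_adj
        )
        pres.append(p)
        absd.append(a)
    # the Eq. itself, inline: a cooler-than-baseline year can legitimately
    # carry a negative (avoided) loss, which labor_loss's guard would reject
    ll = tuple(
        (p + a) * cp.gdp_per_capita_employed / 365.0 for p, a in zip(pres, absd)
    )
    pd_excess = mean_ex.total * p0 * apop_v
    return BurdenResult(
        year=mean_ex.year,
        yll=yll,
        yld=yld,
        daly=dalys,
        wellbeing_cost=wb,
        presenteeism_days=tuple(pres),
        absenteeism_days=tuple(absd),
        labor_loss=ll,
        excess_person_days=pd_excess,
    )


@dataclass
class ScenarioTrajectory:
    """Per-year burden results over a projection horizon, plus cumulative sums."""

    country: str
    scenario: str
    results: list[BurdenResult]

    def cumulative(self, name: str, level: str = "mean") -> float:
        i = _level_index(level)
        return float(sum(getattr(r, name)[i] for r in self.results))

    def series(self, name: str, level: str = "mean") -> np.ndarray:
        i = _level_index(level)
        return np.array([getattr(r, name)[i] for r in self.results])

    @property
    def years(self) -> list[int]:
        return [r.year for r in self.results]


#: prevalence multiplier ramp of the sensitivity mode: linear to 1.3x by 2050
PREVALENCE_RAMP = (2023, 2050, 1.3)


def _prevalence_factor(year: int) -> float:
    y0, y1, top = PREVALENCE_RAMP
    if year <= y0:
        return 1.0
    if year >= y1:
        return top
    return 1.0 + (top - 1.0) * (year - y0) / (y1 - y0)


def project_scenario(
    curve: ExposureResponseCurve,
    scenario: DailySeries,
    clim: Climatology,
    cp: CountryParams,
    bp: BurdenParams | None = None,
    years: Sequence[int] | None = None,
    mode: str = "primary",
    scenario_name: str = "scenario",
    column: str = "tmean",
) -> ScenarioTrajectory:
    """Chain attribution and the burden formulas over a scenario horizon.

    ``mode='primary'`` holds prevalence and population at their base-year
    values; ``mode='sensitivity'`` applies the population forecast and
    ramps OSA prevalence linearly to 1.3x by 2050 (constant after).
    """
    if mode not in ("primary", "sensitivity"):
        raise ValueError("mode must be 'primary' or 'sensitivity'")
    bp = bp or BurdenParams()
    avail = scenario.data["date"].dt.year.unique()
    if years is None:
        years = [int(y) for y in sorted(avail)]
    missing = set(years) - set(int(y) for y in avail)
    if missing:
        raise ValueError(f"scenario missing years: {sorted(missing)}")
    results = []
    for year in years:
        excess = {
            lvl: daily_excess_risk(
                curve, scenario, clim, year=year, level=lvl, column=column
            )
            for lvl in _LEVELS
        }
        if mode == "sensitivity":
            p0 = min(cp.osa_prevalence * _prevalence_factor(year), 1.0)
            apop = cp.population(year, use_forecast=True)
        else:
            p0 = cp.osa_prevalence
            apop = cp.adult_population
        results.append(compute_burden(excess, cp, bp, p0=p0, apop=apop))
    return ScenarioTrajectory(
        country=cp.country, scenario=scenario_name, results=results
    )
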