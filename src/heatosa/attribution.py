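"""Warming attribution: excess OSA risk relative to a historical climatology.

For each calendar day of a target year, the fitted exposure-response curve
is evaluated at that day's temperature and at the 1950-1990 day-of-year
average; the difference in RR — on the RR scale, matching the bracketed
term of the burden formulas — is the daily excess risk.  Summed over the
year and scaled by OSA prevalence and adult population it yields the excess
OSA person-days attributable to warming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import ExposureResponseCurve
from .synthetic import DailySeries

logger = logging.getLogger(__name__)

__all__ = [
    "Climatology",
    "ExcessSeries",
    "climatology_1950_1990",
    "daily_excess_risk",
    "excess_person_days",
]

#: map (month, day) -> day-of-year 1..365 on a non-leap calendar
_DOY_365 = {
    (d.month, d.day): i + 1
    for i, d in enumerate(pd.date_range("2001-01-01", "2001-12-31", freq="D"))
}


def _doy365(dates: pd.Series) -> np.ndarray:
    """Day-of-year index that skips Feb 29 (callers drop it first)."""
    md = list(zip(dates.dt.month, dates.dt.day))
    return np.array([_DOY_365[k] for k in md])


@dataclass
class Climatology:
    """365 day-of-year mean temperatures over a historical window."""

    country: str
    values: np.ndarray  # index 0 = Jan 1
    window: tuple[int, int] = (1950, 1990)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (365,):
            raise ValueError("climatology must have exactly 365 entries")
        if not np.isfinite(self.values).all():
            raise ValueError("climatology must be finite")


@dataclass
class ExcessSeries:
    """Daily RR(T_d) - RR(Thist_d) for one year, plus its sum and mean."""

    year: int
    values: np.ndarray
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (365,):
            raise ValueError("excess series must have exactly 365 entries")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def climatology_1950_1990(
    series: DailySeries,
    window: tuple[int, int] = (1950, 1990),
    column: str = "tmean",
) -> Climatology:
    """Per-day-of-year mean temperature over the window years.

    Feb 29 is dropped before averaging, so every year contributes 365
    entries.  Partial years inside the window still contribute the days
    they cover, but at least one full year of coverage is required.
    """
    df = series.data
    years = df["date"].dt.year
    in_window = (years >= window[0]) & (years <= window[1])
    sub = df[in_window]
    if sub.empty:
        raise ValueError(f"series has no coverage inside {window}")
    sub = sub[~((sub["date"].dt.month == 2) & (sub["date"].dt.day == 29))]
    doy = _doy365(sub["date"])
    sums = np.bincount(doy - 1, weights=sub[column].to_numpy(), minlength=365)
    counts = np.bincount(doy - 1, minlength=365)
    if (counts == 0).any():
        raise ValueError("window coverage does not span a full calendar year")
    return Climatology(series.country, sums / counts, window=window)


def year_temperatures(
    series: DailySeries, year: int, column: str = "tmean"
) -> np.ndarray:
    """The 365 daily temperatures of one calendar year (Feb 29 dropped)."""
    df = series.data
    sub = df[df["date"].dt.year == year]
    sub = sub[~((sub["date"].dt.month == 2) & (sub["date"].dt.day == 29))]
    if len(sub) != 365:
        raise ValueError(f"year {year} has {len(sub)} usable days, need 365")
    return sub.sort_values("date")[column].to_numpy(dtype=float)


def daily_excess_risk(
    curve: ExposureResponseCurve,
    year_series: DailySeries | np.ndarray,
    clim: Climatology,
    year: int | None = None,
    level: str = "mean",
    column: str = "tmean",
) -> ExcessSeries:
    """RR(T_d) - RR(Thist_d) for each of the year's 365 days.

    The curve is interpolated on the RR scale; temperatures outside the
    curve's grid are clipped to the grid ends (flat extrapolation) with the
    clipped-day count recorded and logged.  ``level`` evaluates the curve
    at its point estimate or 95% CI envelope, propagating the curve's
    uncertainty into everything downstream.
    """
    if isinstance(year_series, DailySeries):
        if year is None:
            years = year_series.data["date"].dt.year.unique()
            if len(years) != 1:
                raise ValueError("pass year= when the series spans several years")
            year = int(years[0])
        temps = year_temperatures(year_series, year, column=column)
    else:
        temps = np.asarray(year_series, dtype=float)
        if temps.shape != (365,):
            raise ValueError("temperature array must have 365 entries")
        if year is None:
            raise ValueError("pass year= with a bare temperature array")

    lo, hi = curve.grid[0], curve.grid[-1]
    n_clipped = int(((temps < lo) | (temps > hi)).sum())
    n_clipped += int(((clim.values < lo) | (clim.values > hi)).sum())
    if n_clipped:
        logger.info("year %d: %d day-temperatures clipped to curve grid", year, n_clipped)
    rr_now = curve.rr_at(temps, level=level, clip=True)
    rr_hist = curve.rr_at(clim.values, level=level, clip=True)
    return ExcessSeries(year=year, values=rr_now - rr_hist, n_clipped=n_clipped)


def excess_person_days(excess: ExcessSeries, p0: float, apop: float) -> float:
    """Excess OSA person-days: sum_d excess_d * prevalence * adult population."""
    if not 0 <= p0 <= 1:
        raise ValueError("prevalence must be in [0, 1]")
    if apop < 0:
        raise ValueError("population must be >= 0")
    return excess.total * p0 * apop
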