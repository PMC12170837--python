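"""Synthetic weather, country parameters, and nightly OSA panels.

Real inputs to this kind of analysis — a multi-year nightly panel from an
under-mattress sleep sensor, reanalysis weather and climate-scenario
temperature series — are proprietary or bulky downloads.  This module
generates desk-scale stand-ins with a *known* generative exposure-response,
so that every downstream stage (cross-basis, conditional-Poisson fit, curve
summarisation, attribution, burden) can be tested against ground truth.

The outcome model is multiplicative in risk (log link):

    P(OSA on night d | user u) = p0 * exp( a_u + season(d) + dow(d)
                                 + sum_l gamma_l * s(T_{d-l}) + covariates )

with ``s`` a fixed exposure transform and ``gamma`` the lag-effect vector.
Because the model is log-linear in probability, the cumulative risk ratio
between two temperatures has the closed form

    RR(t1, t2) = exp( sum_l gamma_l * (s(t1) - s(t2)) )

independent of the user, which is what the conditional-Poisson estimator
targets; :func:`calibrate_lag_effects` inverts this identity to hit a
requested RR at a requested temperature contrast exactly.

By default ``s`` lives in the same natural-spline space the fitter uses
(parameter recovery is then exact in expectation); a piecewise-linear truth
is available for misspecification checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .basis import SplineSpec, spline_evaluator

__all__ = [
    "WeatherConfig",
    "CohortConfig",
    "DailySeries",
    "NightlyPanel",
    "ExposureTransform",
    "simulate_country_weather",
    "simulate_cohort",
    "apply_missingness",
    "exposure_transform_from_weather",
    "calibrate_lag_effects",
    "generative_cumulative_rr",
]

#: weather covariate columns carried through panel and design
WEATHER_COVARIATES = (
    "cloud_cover",
    "rel_humidity",
    "pressure",
    "precipitation",
    "wind_speed",
    "pm25",
)

#: fixed half-range between daily mean and daily min/max temperature (degC)
DIURNAL_HALF_RANGE = 4.0


# ---------------------------------------------------------------------------
# containers


@dataclass
class DailySeries:
    """Daily weather for one country: contiguous dates, tmean/tmin/tmax."""

    country: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "date" not in df.columns or "tmean" not in df.columns:
            raise ValueError("DailySeries needs 'date' and 'tmean' columns")
        dates = pd.to_datetime(df["date"])
        diffs = dates.diff().dropna()
        if (diffs != pd.Timedelta(days=1)).any():
            raise ValueError("dates must be daily, contiguous and increasing")
        if {"tmin", "tmax"} <= set(df.columns):
            if ((df["tmin"] > df["tmean"]) | (df["tmean"] > df["tmax"])).any():
                raise ValueError("need tmin <= tmean <= tmax")
        self.data = df.assign(date=dates).reset_index(drop=True)

    @property
    def dates(self) -> pd.Series:
        return self.data["date"]

    @property
    def tmean(self) -> np.ndarray:
        return self.data["tmean"].to_numpy()

    def temperature(self, column: str = "tmean") -> np.ndarray:
        if column not in ("tmean", "tmin", "tmax"):
            raise ValueError("exposure column must be tmean, tmin or tmax")
        return self.data[column].to_numpy()


@dataclass
class NightlyPanel:
    """Per-user per-night outcomes, exposures (with lags) and covariates."""

    data: pd.DataFrame
    exposure: str = "tmean"
    max_lag: int = 4

    def __post_init__(self) -> None:
        df = self.data
        required = {"user_id", "date", "osa"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        if df.duplicated(["user_id", "date"]).any():
            raise ValueError("panel must have one row per user-date")
        for col in ("osa", "osa_severe"):
            if col in df.columns:
                vals = df[col].dropna().unique()
                if not np.isin(vals, (0, 1)).all():
                    raise ValueError(f"{col} must be 0/1/missing")

    @property
    def lag_columns(self) -> list[str]:
        return [self.exposure] + [
            f"{self.exposure}_lag{l}" for l in range(1, self.max_lag + 1)
        ]

    def lag_matrix(self) -> np.ndarray:
        return self.data[self.lag_columns].to_numpy(dtype=float)

    def covariate_columns(self) -> list[str]:
        return [c for c in WEATHER_COVARIATES if c in self.data.columns]


# ---------------------------------------------------------------------------
# weather


@dataclass(frozen=True)
class WeatherConfig:
    """Generator settings for one country's daily temperature series.

    ``noise_sd`` is the stationary standard deviation of the AR(1)
    day-to-day anomaly; ``trend_per_decade`` is a linear warming trend.
    """

    country: str = "SYN"
    start_year: int = 2019
    end_year: int = 2023
    mean_temp: float = 14.0
    seasonal_amplitude: float = 9.0
    noise_sd: float = 3.0
    noise_ar: float = 0.6
    trend_per_decade: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        vals = (
            self.mean_temp,
            self.seasonal_amplitude,
            self.noise_sd,
            self.noise_ar,
            self.trend_per_decade,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("weather config values must be finite")
        if self.seasonal_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise scale must be >= 0")
        if not (0 <= self.noise_ar < 1):
            raise ValueError("autocorrelation must be in [0, 1)")
        if self.end_year < self.start_year:
            raise ValueError("end year must be >= start year")


def _seasonal_cycle(doy: np.ndarray, amplitude: float, peak_doy: float) -> np.ndarray:
    return amplitude * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)


def simulate_country_weather(cfg: WeatherConfig) -> DailySeries:
    """Daily mean/min/max temperatures plus simple weather covariates.

    tmean = annual mean + seasonal sinusoid (peak mid-July) + AR(1) noise
    + trend; tmin/tmax are tmean -/+ a fixed 4 degC diurnal half-range.
    Deterministic given the config (seed included).
    """
    dates = pd.date_range(
        f"{cfg.start_year}-01-01", f"{cfg.end_year}-12-31", freq="D"
    )
    n = len(dates)
    doy = dates.dayofyear.to_numpy().astype(float)
    years_elapsed = (dates - dates[0]).days.to_numpy() / 365.25

    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x5EA]))
    if cfg.noise_sd > 0:
        z = rng.standard_normal(n)
        innov_sd = cfg.noise_sd * math.sqrt(1 - cfg.noise_ar**2)
        noise = np.empty(n)
        noise[0] = cfg.noise_sd * z[0]
        for i in range(1, n):
            noise[i] = cfg.noise_ar * noise[i - 1] + innov_sd * z[i]
    else:
        noise = np.zeros(n)

    tmean = (
        cfg.mean_temp
        + _seasonal_cycle(doy, cfg.seasonal_amplitude, peak_doy=196.0)
        + noise
        + cfg.trend_per_decade / 10.0 * years_elapsed
    )

    cloud = np.clip(
        0.55 - 0.15 * np.cos(2 * np.pi * (doy - 15) / 365.25)
        + 0.15 * rng.standard_normal(n),
        0.0,
        1.0,
    )
    rh = np.clip(
        70 + 8 * np.cos(2 * np.pi * (doy - 15) / 365.25) + 6 * rng.standard_normal(n),
        5,
        100,
    )
    pressure = 1013 + 6 * rng.standard_normal(n)
    precip = np.maximum(rng.gamma(0.6, 3.0, size=n) - 1.0, 0.0)
    wind = rng.gamma(2.5, 1.6, size=n)
    pm25 = np.maximum(rng.lognormal(2.2, 0.5, size=n), 0.5)

    df = pd.DataFrame(
        {
            "date": dates,
            "tmean": tmean,
            "tmin": tmean - DIURNAL_HALF_RANGE,
            "tmax": tmean + DIURNAL_HALF_RANGE,
            "cloud_cover": cloud,
            "rel_humidity": rh,
            "pressure": pressure,
            "precipitation": precip,
            "wind_speed": wind,
            "pm25": pm25,
        }
    )
    return DailySeries(country=cfg.country, data=df)


# ---------------------------------------------------------------------------
# exposure transform and calibration


@dataclass(frozen=True)
class ExposureTransform:
    """The generative temperature transform ``s``.

    ``kind='spline'`` projects a smooth monotone heat-response shape onto
    the same natural-spline space the fitter uses (so the fitted model
    class contains the truth); ``kind='piecewise_linear'`` is a hinge truth
    outside that space, for misspecification checks.
    """

    kind: str
    spec: SplineSpec | None = None
    coef: tuple[float, ...] = ()
    hinge: float = 15.0
    hinge_scale: float = 10.0

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        if self.kind == "piecewise_linear":
            out = np.maximum(t - self.hinge, 0.0) / self.hinge_scale
        else:
            fn = spline_evaluator(self.spec)
            out = fn(np.atleast_1d(t)) @ np.asarray(self.coef)
        return float(out.reshape(-1)[0]) if t.ndim == 0 else out


def _base_shape(t: np.ndarray) -> np.ndarray:
    # smooth, flat-cold / rising-warm heat response
    return np.logaddexp(0.0, (t - 15.0) / 6.0)


def exposure_transform_from_weather(
    weather: DailySeries,
    kind: str = "spline",
    spline_df: int = 4,
    exposure: str = "tmean",
    window_nights: int | None = None,
) -> ExposureTransform:
    """Build the generative transform from a weather series.

    ``window_nights`` restricts the knot-placement quantiles to the final
    nights of the series — the stretch a cohort will actually observe — so
    the generative spline space coincides with the one a fitter resolves
    on the resulting panel.
    """
    if kind == "piecewise_linear":
        return ExposureTransform(kind=kind)
    t = weather.temperature(exposure)
    if window_nights is not None:
        t = t[-window_nights:]
    spec = SplineSpec(df=spline_df, center=float(np.median(t))).resolve(t)
    fn = spline_evaluator(spec)
    grid = np.linspace(spec.boundary[0], spec.boundary[1], 401)
    design = np.c_[np.ones(grid.size), fn(grid)]
    coef, *_ = np.linalg.lstsq(design, _base_shape(grid), rcond=None)
    return ExposureTransform(kind="spline", spec=spec, coef=tuple(coef[1:]))


#: default split of the cumulative effect over lags 0..4 (sums to 1)
DEFAULT_LAG_WEIGHTS = (0.35, 0.25, 0.18, 0.13, 0.09)


def calibrate_lag_effects(
    transform: ExposureTransform,
    rr: float,
    t_high: float = 27.3,
    t_low: float = 6.4,
    lag_weights: Sequence[float] = DEFAULT_LAG_WEIGHTS,
) -> tuple[float, ...]:
    """Lag-effect vector whose cumulative RR(t_high vs t_low) equals ``rr``."""
    if rr <= 0:
        raise ValueError("rr must be positive")
    w = np.asarray(lag_weights, dtype=float)
    w = w / w.sum()
    delta = float(transform(t_high) - transform(t_low))
    if delta == 0:
        raise ValueError("transform does not separate the two temperatures")
    return tuple(math.log(rr) / delta * w)


def generative_cumulative_rr(
    cfg: "CohortConfig", t1, t2, outcome: str = "osa"
) -> np.ndarray | float:
    """Closed-form cumulative risk ratio implied by the generative model."""
    lag = cfg.lag_effects if outcome == "osa" else cfg.lag_effects_severe
    total = float(np.sum(lag))
    s1 = cfg.transform(t1)
    s2 = cfg.transform(t2)
    out = np.exp(total * (np.asarray(s1) - np.asarray(s2)))
    return float(out) if out.size == 1 else out


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings for the nightly OSA panel.

    Baseline nightly probabilities default to the observed prevalence of
    moderate-to-severe (25.4%) and severe (8.9%) OSA; total sleep time is
    Normal(7.4, 0.8) hours.  Effect sizes are on the log-risk scale.
    """

    n_users: int = 200
    nights_per_user: int = 365
    baseline_prob: float = 0.254
    baseline_prob_severe: float = 0.089
    intercept_sd: float = 0.25
    seasonal_amplitude: float = 0.08
    dow_effects: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.03, 0.05, 0.02)
    transform: ExposureTransform = field(
        default_factory=lambda: ExposureTransform(kind="piecewise_linear")
    )
    lag_effects: tuple[float, ...] = (0.0,) * 5
    lag_effects_severe: tuple[float, ...] = (0.0,) * 5
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    tst_mean: float = 7.4
    tst_sd: float = 0.8
    exposure: str = "tmean"
    apply_missingness: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.baseline_prob, self.baseline_prob_severe):
            if not 0 < p < 1:
                raise ValueError("baseline probabilities must be in (0, 1)")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries (Monday first)")
        if len(self.lag_effects) != len(self.lag_effects_severe):
            raise ValueError("lag vectors must have equal length")

    @property
    def max_lag(self) -> int:
        return len(self.lag_effects) - 1

    @classmethod
    def calibrated(
        cls,
        weather: DailySeries,
        rr: float = 1.45,
        rr_severe: float = 1.49,
        t_high: float = 27.3,
        t_low: float = 6.4,
        truth: str = "spline",
        **kwargs,
    ) -> "CohortConfig":
        """Config whose generative cumulative RR at the given temperature
        contrast equals ``rr`` (and ``rr_severe`` for the severe outcome)."""
        transform = exposure_transform_from_weather(
            weather,
            kind=truth,
            exposure=kwargs.get("exposure", "tmean"),
            window_nights=kwargs.get("nights_per_user"),
        )
        return cls(
            transform=transform,
            lag_effects=calibrate_lag_effects(transform, rr, t_high, t_low),
            lag_effects_severe=calibrate_lag_effects(
                transform, rr_severe, t_high, t_low
            ),
            **kwargs,
        )


def simulate_cohort(weather: DailySeries, cfg: CohortConfig) -> NightlyPanel:
    """Draw a nightly panel from the generative model described above.

    All users share the final ``nights_per_user`` days of the weather
    series (which must also cover the ``max_lag`` preceding days).  Random
    streams are split per user, so enlarging the cohort leaves existing
    users' trajectories unchanged.
    """
    max_lag = cfg.max_lag
    temps = weather.temperature(cfg.exposure)
    n_weather = len(temps)
    if n_weather < cfg.nights_per_user + max_lag:
        raise ValueError(
            "weather must cover all cohort nights plus the preceding lag window"
        )
    start = n_weather - cfg.nights_per_user
    idx = np.arange(start, n_weather)
    dates = weather.dates.iloc[idx].reset_index(drop=True)

    s_vals = np.asarray(cfg.transform(temps), dtype=float)
    lag = np.asarray(cfg.lag_effects)
    lag_sev = np.asarray(cfg.lag_effects_severe)
    eta_temp = np.zeros(len(idx))
    eta_temp_sev = np.zeros(len(idx))
    for l in range(max_lag + 1):
        eta_temp += lag[l] * s_vals[idx - l]
        eta_temp_sev += lag_sev[l] * s_vals[idx - l]
    # center the temperature term at its window mean so baseline_prob stays
    # the typical night's probability
    eta_temp -= eta_temp.mean()
    eta_temp_sev -= eta_temp_sev.mean()

    doy = dates.dt.dayofyear.to_numpy().astype(float)
    eta_shared = _seasonal_cycle(doy, cfg.seasonal_amplitude, peak_doy=15.0)
    dow = dates.dt.dayofweek.to_numpy()
    eta_shared = eta_shared + np.asarray(cfg.dow_effects)[dow]
    for name, effect in cfg.covariate_effects.items():
        v = weather.data[name].to_numpy()[idx]
        sd = v.std()
        if sd > 0:
            eta_shared = eta_shared + effect * (v - v.mean()) / sd

    eta = eta_shared + eta_temp
    eta_sev = eta_shared + eta_temp_sev

    n_nights = cfg.nights_per_user
    n_rows = cfg.n_users * n_nights
    osa = np.empty(n_rows, dtype=np.int8)
    sev = np.empty(n_rows, dtype=np.int8)
    tst = np.empty(n_rows)
    intercepts = np.empty(cfg.n_users)

    streams = np.random.SeedSequence([int(cfg.seed), 0xC04]).spawn(cfg.n_users)
    for u, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        a_u = rng.normal(0.0, cfg.intercept_sd) if cfg.intercept_sd > 0 else 0.0
        intercepts[u] = a_u
        p = np.clip(cfg.baseline_prob * np.exp(a_u + eta), 0.0, 0.995)
        p_sev = np.minimum(
            np.clip(cfg.baseline_prob_severe * np.exp(a_u + eta_sev), 0.0, 0.995), p
        )
        u_draw = rng.random(n_nights)
        sl = slice(u * n_nights, (u + 1) * n_nights)
        osa[sl] = u_draw < p
        sev[sl] = u_draw < p_sev
        tst[sl] = rng.normal(cfg.tst_mean, cfg.tst_sd, size=n_nights)

    frame = {
        "user_id": np.repeat(np.arange(cfg.n_users), n_nights),
        "date": np.tile(dates.to_numpy(), cfg.n_users),
        "osa": osa.astype(float),
        "osa_severe": sev.astype(float),
        "tst_h": tst,
        cfg.exposure: np.tile(temps[idx], cfg.n_users),
    }
    for l in range(1, max_lag + 1):
        frame[f"{cfg.exposure}_lag{l}"] = np.tile(temps[idx - l], cfg.n_users)
    for name in WEATHER_COVARIATES:
        if name in weather.data.columns:
            frame[name] = np.tile(weather.data[name].to_numpy()[idx], cfg.n_users)
    frame["ahi_missing"] = np.zeros(n_rows, dtype=bool)
    panel = NightlyPanel(
        pd.DataFrame(frame), exposure=cfg.exposure, max_lag=max_lag
    )
    if cfg.apply_missingness:
        panel = apply_missingness(panel)
    return panel


def apply_missingness(
    panel: NightlyPanel,
    temperature_dependent: bool = False,
    tst_heat_slope: float = 0.05,
    tst_heat_threshold: float = 25.0,
) -> NightlyPanel:
    """Blank the nightly AHI-based indicators where sleep is too short.

    The AHI cannot be computed on nights with under five hours of sleep, so
    those indicators become missing.  With ``temperature_dependent`` on,
    total sleep time is first shifted down by ``tst_heat_slope`` hours per
    degC above ``tst_heat_threshold`` before thresholding, emulating the
    heat/short-sleep association for missingness-bias sensitivity runs (the
    slope is a free parameter of the emulation, not an estimate).
    """
    df = panel.data.copy()
    tst = df["tst_h"].to_numpy(dtype=float)
    if temperature_dependent:
        t = df[panel.exposure].to_numpy(dtype=float)
        tst = tst - tst_heat_slope * np.maximum(t - tst_heat_threshold, 0.0)
        df["tst_h"] = tst
    missing = tst < 5.0
    df["ahi_missing"] = missing
    for col in ("osa", "osa_severe"):
        if col in df.columns:
            vals = df[col].to_numpy(dtype=float).copy()
            vals[missing] = np.nan
            df[col] = vals
    return NightlyPanel(df, exposure=panel.exposure, max_lag=panel.max_lag)
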