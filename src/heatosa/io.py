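"""Flat-file interchange: CSV tables, YAML configs, JSON manifests.

All tables are plain CSV with documented headers and ISO-8601 dates.
Files written by this package carry a single ``# heatosa: key=value``
metadata comment line (seed, kind) ahead of the header; readers skip any
leading ``#`` comments, so hand-made files without the sidecar also parse.

Fitted models serialise to JSON (coefficients, covariance, cross-basis
spec), and exposure-response curves to CSV via
:meth:`heatosa.curves.ExposureResponseCurve.to_csv` — the curve CSV is the
interchange boundary, so externally published curves can be slotted into
attribution and burden stages without refitting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

from .basis import CrossBasisSpec, SplineSpec
from .burden import BurdenParams, CountryParams
from .model import FitResult
from .synthetic import DailySeries, NightlyPanel

__all__ = [
    "read_weather",
    "write_weather",
    "read_panel",
    "write_panel",
    "read_country_params",
    "write_country_params",
    "save_fit",
    "load_fit",
    "RunConfig",
    "load_config",
    "write_manifest",
]

PANEL_REQUIRED = ("user_id", "date", "osa")
WEATHER_REQUIRED = ("date", "tmean")
COUNTRY_REQUIRED = (
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


def _write_csv(df: pd.DataFrame, path, kind: str, seed=None) -> None:
    meta = f"# heatosa: kind={kind}"
    if seed is not None:
        meta += f" seed={seed}"
    with open(path, "w") as fh:
        fh.write(meta + "\n")
        df.to_csv(fh, index=False)


def _read_csv(path, required, kind: str, known=None) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} file {path} missing mandatory columns: {missing}")
    if known is not None:
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            logger.warning("%s file %s: ignoring unknown columns %s", kind, path, unknown)
    if "date" in df.columns:
        parsed = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
        bad = np.flatnonzero(parsed.isna() & df["date"].notna())
        if bad.size:
            raise ValueError(
                f"{kind} file {path}: unparseable dates at rows {bad[:10].tolist()}"
            )
        df["date"] = parsed
    return df


def write_weather(series: DailySeries, path, seed=None) -> None:
    df = series.data.copy()
    df.insert(0, "country", series.country)
    _write_csv(df, path, "weather", seed=seed)


def read_weather(path) -> DailySeries:
    df = _read_csv(path, WEATHER_REQUIRED, "weather")
    country = str(df["country"].iloc[0]) if "country" in df.columns else "NA"
    return DailySeries(country=country, data=df.drop(columns=["country"], errors="ignore"))


def write_panel(panel: NightlyPanel, path, seed=None) -> None:
    _write_csv(panel.data, path, "panel", seed=seed)


def read_panel(path, exposure: str = "tmean", max_lag: int = 4) -> NightlyPanel:
    df = _read_csv(path, PANEL_REQUIRED, "panel")
    lag_cols = [f"{exposure}_lag{l}" for l in range(1, max_lag + 1)]
    missing = [c for c in [exposure] + lag_cols if c not in df.columns]
    if missing:
        raise ValueError(f"panel file {path} missing exposure columns: {missing}")
    return NightlyPanel(df, exposure=exposure, max_lag=max_lag)


def write_country_params(params: list[CountryParams], path) -> None:
    rows = []
    for cp in params:
        d = asdict(cp)
        d.pop("population_forecast")
        rows.append(d)
    _write_csv(pd.DataFrame(rows), path, "country-params")


def read_country_params(path) -> dict[str, CountryParams]:
    df = _read_csv(
        path, COUNTRY_REQUIRED, "country-params", known=COUNTRY_REQUIRED
    )
    out = {}
    for i, row in df.iterrows():
        try:
            cp = CountryParams(
                **{k: row[k] if k == "country" else float(row[k]) for k in COUNTRY_REQUIRED}
            )
        except ValueError as err:
            raise ValueError(f"country-params row {i}: {err}") from None
        out[cp.country] = cp
    return out


# ---------------------------------------------------------------------------
# fit serialisation


def _spec_to_dict(spec: CrossBasisSpec) -> dict:
    return {
        "exposure": {
            "df": spec.exposure.df,
            "knots": list(spec.exposure.knots or ()),
            "boundary": list(spec.exposure.boundary or ()),
        },
        "max_lag": spec.max_lag,
        "reference": spec.reference,
    }


def _spec_from_dict(d: dict) -> CrossBasisSpec:
    e = d["exposure"]
    return CrossBasisSpec(
        exposure=SplineSpec(
            df=e["df"],
            knots=tuple(e["knots"]) or None,
            boundary=tuple(e["boundary"]) or None,
        ),
        max_lag=d["max_lag"],
        reference=d["reference"],
    )


def save_fit(fit: FitResult, path) -> None:
    payload = {
        "params": fit.params.tolist(),
        "cov_params": fit.cov_params.tolist(),
        "llf": fit.llf,
        "n_iter": fit.n_iter,
        "converged": fit.converged,
        "nobs": fit.nobs,
        "n_strata": fit.n_strata,
        "n_dropped_strata": fit.n_dropped_strata,
        "columns": fit.columns,
        "crossbasis_columns": fit.crossbasis_columns,
        "crossbasis_spec": _spec_to_dict(fit.crossbasis_spec)
        if fit.crossbasis_spec
        else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_fit(path) -> FitResult:
    d = json.loads(Path(path).read_text())
    spec = d.pop("crossbasis_spec")
    return FitResult(
        params=np.asarray(d.pop("params")),
        cov_params=np.asarray(d.pop("cov_params")),
        crossbasis_spec=_spec_from_dict(spec) if spec else None,
        **d,
    )


# ---------------------------------------------------------------------------
# run configuration and manifests


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from one YAML file."""

    seed: int = 0
    exposure: str = "mean"  # mean | min | max daily temperature
    max_lag: int = 4
    spline_df: int = 4
    reference_percentile: float = 25.0
    weather: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    attribution_window: tuple[int, int] = (1950, 1990)
    attribution_year: int | None = None
    scenarios: list = field(default_factory=list)
    burden_mode: str = "primary"
    curve_grid_points: int = 151

    def __post_init__(self) -> None:
        if self.exposure not in ("mean", "min", "max"):
            raise ValueError("exposure must be one of mean, min, max")
        self.attribution_window = tuple(int(v) for v in self.attribution_window)

    @property
    def exposure_column(self) -> str:
        return {"mean": "tmean", "min": "tmin", "max": "tmax"}[self.exposure]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def config_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(path, stage: str, inputs: dict, seed, extra: dict | None = None) -> None:
    """Per-stage JSON manifest: inputs, seed, versions, stage counters."""
    import heatosa

    payload = {
        "stage": stage,
        "seed": seed,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "versions": {
            "heatosa": heatosa.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
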