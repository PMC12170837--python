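"""Case-time-series model: conditional Poisson with absorbed strata.

The case-time-series design conditions each participant's outcome series on
participant x calendar-year x calendar-month strata, absorbing individual
baseline risk and shared long-term trends into stratum intercepts.  With a
log link the stratum intercepts can be profiled out of the Poisson
likelihood analytically, leaving the multinomial-form objective

    l(beta) = sum_i y_i eta_i - sum_s Y_s log sum_{i in s} exp(eta_i)

which this module maximises by Newton-Raphson.  Strata with zero outcome
total carry no information and are dropped.  The binary nightly outcome is
treated with the Poisson (log-link) likelihood — the standard absorbing
choice for this design at low nightly probability — so the coefficients are
log rate (risk) ratios.

The public surface follows the statsmodels idiom: build a
:class:`CaseTimeSeriesModel` from a nightly panel, call ``fit()``, and read
estimates, covariance and derived exposure-response summaries off the
returned :class:`CaseTimeSeriesResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .basis import (
    BasisMatrix,
    CrossBasisSpec,
    SplineSpec,
    cross_basis,
    natural_spline_basis,
)
from .synthetic import NightlyPanel

logger = logging.getLogger(__name__)

__all__ = [
    "StratumIndex",
    "FitResult",
    "CaseTimeSeriesModel",
    "CaseTimeSeriesResults",
    "assign_strata",
    "build_design",
    "fit_conditional_poisson",
    "fit_subgroup",
]


# ---------------------------------------------------------------------------
# strata


@dataclass
class StratumIndex:
    """Row-to-stratum assignment for (user, year, month) strata."""

    codes: np.ndarray  # int codes, one per row
    labels: list[tuple]  # code -> (user, year, month)
    outcome_totals: np.ndarray  # per stratum, NaN-aware sum of outcome
    row_counts: np.ndarray

    @property
    def n_strata(self) -> int:
        return len(self.labels)

    @property
    def informative(self) -> np.ndarray:
        """Strata with at least one event and at least one usable row."""
        return (self.outcome_totals > 0) & (self.row_counts > 0)


def assign_strata(panel: NightlyPanel | pd.DataFrame, outcome: str = "osa") -> StratumIndex:
    """Label each row with its (user, calendar year, calendar month) stratum."""
    df = panel.data if isinstance(panel, NightlyPanel) else panel
    if df["date"].isna().any():
        raise ValueError("panel has missing dates")
    dates = pd.to_datetime(df["date"])
    key = pd.MultiIndex.from_arrays(
        [df["user_id"], dates.dt.year, dates.dt.month],
        names=["user_id", "year", "month"],
    )
    codes, uniques = pd.factorize(key, sort=True)
    y = df[outcome].to_numpy(dtype=float)
    usable = ~np.isnan(y)
    totals = np.bincount(codes[usable], weights=y[usable], minlength=len(uniques))
    counts = np.bincount(codes[usable], minlength=len(uniques))
    return StratumIndex(
        codes=codes,
        labels=list(uniques),
        outcome_totals=totals,
        row_counts=counts,
    )


# ---------------------------------------------------------------------------
# design


@dataclass
class DesignInfo:
    """Design matrix with column bookkeeping (which columns form which block)."""

    matrix: np.ndarray
    columns: list[str]
    groups: dict[str, list[int]]  # block name -> column indices
    crossbasis_spec: CrossBasisSpec
    dropped: list[str] = field(default_factory=list)

    def group_matrix(self, name: str) -> np.ndarray:
        return self.matrix[:, self.groups[name]]


DEFAULT_COVARIATE_DF = 4
DOY_DF = 4


def _covariate_spec(x: np.ndarray, df: int) -> SplineSpec:
    """Quantile-knot spline spec, degrading df for tie-heavy covariates
    (e.g. zero-inflated precipitation) whose quantile knots collide with
    each other or the boundary."""
    try:
        return SplineSpec(df=df).resolve(x)
    except ValueError:
        lo, hi = float(np.nanmin(x)), float(np.nanmax(x))
        probs = np.linspace(0, 1, df + 1)[1:-1]
        q = np.quantile(x[np.isfinite(x)], probs)
        knots = sorted({float(v) for v in q if lo < v < hi})
        if knots:
            logger.info(
                "reduced covariate spline to %d df (tied quantile knots)",
                len(knots) + 1,
            )
            return SplineSpec(knots=tuple(knots), boundary=(lo, hi))
        logger.info("covariate has too few distinct values; using linear term")
        return SplineSpec(df=1, boundary=(lo, hi))


def build_design(
    panel: NightlyPanel,
    cb: BasisMatrix,
    covariates: Sequence[str] = (),
    covariate_df: int = DEFAULT_COVARIATE_DF,
    rows: np.ndarray | None = None,
) -> DesignInfo:
    """Assemble cross-basis + day-of-year spline + day-of-week indicators
    + one natural spline per continuous covariate.

    ``rows`` restricts to the usable rows (after missing-outcome removal);
    covariate splines place their knots on those rows.  Constant columns
    (degenerate on the usable rows) are dropped with a warning — except
    cross-basis columns, which are protected.
    """
    df = panel.data if rows is None else panel.data.iloc[rows]
    cbv = cb.values if rows is None else cb.values[rows]
    n = len(df)

    blocks: list[np.ndarray] = [cbv]
    names = [f"cb_b{j}_lag{l}" for (j, l) in cb.labels]
    groups = {"crossbasis": list(range(cbv.shape[1]))}

    dates = pd.to_datetime(df["date"])
    doy = dates.dt.dayofyear.to_numpy(dtype=float)
    doy_basis = natural_spline_basis(doy, SplineSpec(df=DOY_DF)).values
    start = len(names)
    blocks.append(doy_basis)
    names += [f"doy_s{j}" for j in range(doy_basis.shape[1])]
    groups["doy"] = list(range(start, len(names)))

    dow = dates.dt.dayofweek.to_numpy()
    dow_block = np.zeros((n, 6))
    for d in range(1, 7):  # Monday is the reference level
        dow_block[:, d - 1] = dow == d
    start = len(names)
    blocks.append(dow_block)
    names += [f"dow_{d}" for d in range(1, 7)]
    groups["dow"] = list(range(start, len(names)))

    for cov in covariates:
        if cov == "tst_dev":
            tst = df["tst_h"].to_numpy(dtype=float)
            user_mean = df.groupby("user_id")["tst_h"].transform("mean").to_numpy()
            x = tst - user_mean
        else:
            if cov not in df.columns:
                raise ValueError(f"covariate '{cov}' not in panel")
            x = df[cov].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            logger.warning("covariate %s constant on usable rows; dropped", cov)
            continue
        basis = natural_spline_basis(x, _covariate_spec(x, covariate_df)).values
        start = len(names)
        blocks.append(basis)
        names += [f"{cov}_s{j}" for j in range(basis.shape[1])]
        groups[cov] = list(range(start, len(names)))

    total = sum(b.shape[1] for b in blocks)
    X = np.empty((n, total))
    pos = 0
    for b in blocks:
        X[:, pos : pos + b.shape[1]] = b
        pos += b.shape[1]

    # drop columns that are constant on the usable rows (a stratum-absorbed
    # model cannot identify them); cross-basis columns are protected
    keep = np.ptp(X, axis=0) > 0
    protected = np.zeros(X.shape[1], dtype=bool)
    protected[groups["crossbasis"]] = True
    if (~keep & protected).any():
        bad = [names[i] for i in np.flatnonzero(~keep & protected)]
        raise ValueError(f"cross-basis columns are degenerate: {bad}")
    dropped = [names[i] for i in np.flatnonzero(~keep)]
    if dropped:
        logger.warning("dropping constant design columns: %s", dropped)
        keep_idx = np.flatnonzero(keep)
        remap = {old: new for new, old in enumerate(keep_idx)}
        X = X[:, keep_idx]
        names = [names[i] for i in keep_idx]
        groups = {
            g: [remap[i] for i in idx if i in remap] for g, idx in groups.items()
        }
        groups = {g: idx for g, idx in groups.items() if idx}
    return DesignInfo(
        matrix=X,
        columns=names,
        groups=groups,
        crossbasis_spec=cb.spec,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# fitter


@dataclass
class FitResult:
    """Estimates from the absorbed conditional-Poisson fit."""

    params: np.ndarray
    cov_params: np.ndarray
    llf: float
    n_iter: int
    converged: bool
    nobs: int
    n_strata: int
    n_dropped_strata: int
    columns: list[str] = field(default_factory=list)
    crossbasis_columns: list[int] = field(default_factory=list)
    crossbasis_spec: CrossBasisSpec | None = None

    def __post_init__(self) -> None:
        k = len(self.params)
        if self.cov_params.shape != (k, k):
            raise ValueError("covariance shape does not match coefficients")


def _drop_collinear(X: np.ndarray, names: list[str], protected: np.ndarray):
    """Rank detection via pivoted Cholesky of the column Gram matrix;
    returns kept column indices (equivalent to pivoted-QR rank on X but
    O(nk^2 + k^3) with a k x k factorisation)."""
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    Xn = X / norms
    gram = Xn.T @ Xn
    _, piv, rank, _ = scipy.linalg.lapack.dpstrf(
        gram, tol=gram.shape[0] * np.finfo(float).eps, lower=0
    )
    rank = int(rank)
    keep = np.zeros(X.shape[1], dtype=bool)
    keep[piv[:rank] - 1] = True
    if (~keep & protected).any():
        bad = [names[i] for i in np.flatnonzero(~keep & protected)]
        raise ValueError(f"cross-basis columns collinear with adjustments: {bad}")
    if not keep.all():
        logger.warning(
            "removed collinear columns: %s", [names[i] for i in np.flatnonzero(~keep)]
        )
    return np.flatnonzero(keep)


def fit_conditional_poisson(
    y: np.ndarray,
    X: np.ndarray,
    strata: np.ndarray,
    columns: list[str] | None = None,
    protected: Sequence[int] = (),
    max_iter: int = 100,
    score_tol: float = 1e-8,
    llf_rtol: float = 1e-10,
) -> FitResult:
    """Maximise the stratum-profiled Poisson likelihood by Newton-Raphson.

    ``strata`` are integer codes; strata whose outcome total is zero are
    dropped (they contribute a constant).  The returned covariance is the
    inverse observed information of the profiled likelihood.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    strata = np.asarray(strata)
    if np.isnan(y).any():
        raise ValueError("missing outcomes must be removed before fitting")
    columns = columns or [f"x{i}" for i in range(X.shape[1])]

    order = np.argsort(strata, kind="stable")
    y_s, X_s, s_s = y[order], X[order], strata[order]
    starts = np.flatnonzero(np.r_[True, np.diff(s_s) != 0])
    totals = np.add.reduceat(y_s, starts)
    n_strata_all = starts.size
    informative = totals > 0
    n_dropped = int((~informative).sum())
    if informative.sum() == 0:
        raise ValueError("no informative strata (no stratum has an event)")

    # keep rows of informative strata only
    group_id = np.cumsum(np.r_[0, np.diff(s_s) != 0])
    row_keep = informative[group_id]
    y_s, X_s, group_id = y_s[row_keep], X_s[row_keep], group_id[row_keep]
    starts = np.flatnonzero(np.r_[True, np.diff(group_id) != 0])
    totals = totals[informative]
    group_id = np.cumsum(np.r_[0, np.diff(group_id) != 0])

    protected_mask = np.zeros(X_s.shape[1], dtype=bool)
    protected_mask[list(protected)] = True
    kept = _drop_collinear(X_s, columns, protected_mask)
    X_s = X_s[:, kept]
    columns = [columns[i] for i in kept]
    protected_kept = [int(np.searchsorted(kept, p)) for p in protected if p in kept]

    k = X_s.shape[1]
    beta = np.zeros(k)
    llf = -np.inf
    converged = False
    it = 0

    def profile_llf_parts(beta):
        eta = X_s @ beta
        m = np.maximum.reduceat(eta, starts)
        e = np.exp(eta - m[group_id])
        S = np.add.reduceat(e, starts)
        llf = float(y_s @ eta - totals @ (np.log(S) + m))
        w = totals[group_id] * e / S[group_id]
        return llf, w

    for it in range(1, max_iter + 1):
        llf_new, w = profile_llf_parts(beta)
        score = X_s.T @ (y_s - w)
        XW = X_s * w[:, None]
        G = np.add.reduceat(XW, starts, axis=0)
        H = X_s.T @ XW - G.T @ (G / totals[:, None])
        if np.abs(score).max() < score_tol or (
            np.isfinite(llf) and abs(llf_new - llf) <= llf_rtol * (abs(llf) + 1e-12)
        ):
            llf = llf_new
            converged = True
            break
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        # step-halving line search on the profiled likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            llf_cand, _ = profile_llf_parts(cand)
            if llf_cand >= llf_new - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        llf = llf_new
        if np.abs(beta).max() > 50:
            logger.warning("coefficients diverging; possible separation")
            break

    if not converged:
        logger.warning("conditional Poisson fit did not converge in %d iterations", it)

    _, w = profile_llf_parts(beta)
    XW = X_s * w[:, None]
    G = np.add.reduceat(XW, starts, axis=0)
    H = X_s.T @ XW - G.T @ (G / totals[:, None])
    cov = np.linalg.pinv(H)
    cov = (cov + cov.T) / 2
    return FitResult(
        params=beta,
        cov_params=cov,
        llf=llf,
        n_iter=it,
        converged=converged,
        nobs=int(y_s.size),
        n_strata=int(totals.size),
        n_dropped_strata=n_dropped,
        columns=columns,
        crossbasis_columns=protected_kept,
    )


# ---------------------------------------------------------------------------
# model / results


DEFAULT_COVARIATES = (
    "cloud_cover",
    "rel_humidity",
    "pressure",
    "precipitation",
    "wind_speed",
    "pm25",
    "tst_dev",
)


class CaseTimeSeriesModel:
    """Distributed-lag case-time-series model for a nightly OSA panel.

    Parameters
    ----------
    panel
        Nightly panel with outcome, exposure lags, and covariates.
    outcome
        Outcome column, ``"osa"`` (AHI >= 15) or ``"osa_severe"`` (>= 30).
    crossbasis
        Exposure x lag cross-basis specification; unresolved parts (knots,
        boundary, reference) are filled from the fitting data, with the
        reference defaulting to the 25th percentile of exposure.
    covariates
        Continuous confounders adjusted with 4-df natural splines;
        ``"tst_dev"`` means nightly total sleep time minus the user mean.
        Covariates absent from the panel are silently skipped.
    """

    def __init__(
        self,
        panel: NightlyPanel,
        outcome: str = "osa",
        crossbasis: CrossBasisSpec | None = None,
        covariates: Sequence[str] | None = None,
    ) -> None:
        self.panel = panel
        self.outcome = outcome
        if covariates is None:
            covariates = [
                c
                for c in DEFAULT_COVARIATES
                if c == "tst_dev" or c in panel.data.columns
            ]
            if "tst_h" not in panel.data.columns:
                covariates = [c for c in covariates if c != "tst_dev"]
        self.covariates = list(covariates)
        spec = crossbasis or CrossBasisSpec(max_lag=panel.max_lag)
        if spec.max_lag != panel.max_lag:
            raise ValueError("crossbasis max_lag does not match panel lags")
        lagmat = panel.lag_matrix()
        self._lagmat = lagmat
        self.crossbasis_spec = spec.resolve(lagmat[:, 0])

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, exposure: str = "tmean", max_lag: int = 4, **kwargs
    ) -> "CaseTimeSeriesModel":
        panel = NightlyPanel(data, exposure=exposure, max_lag=max_lag)
        return cls(panel, **kwargs)

    def fit(self, **fit_kwargs) -> "CaseTimeSeriesResults":
        df = self.panel.data
        y = df[self.outcome].to_numpy(dtype=float)
        usable = np.flatnonzero(~np.isnan(y))  # complete-case within stratum
        cb = cross_basis(self._lagmat, self.crossbasis_spec)
        design = build_design(self.panel, cb, self.covariates, rows=usable)
        strata = assign_strata(self.panel, outcome=self.outcome)
        res = fit_conditional_poisson(
            y[usable],
            design.matrix,
            strata.codes[usable],
            columns=design.columns,
            protected=design.groups["crossbasis"],
            **fit_kwargs,
        )
        res.crossbasis_spec = self.crossbasis_spec
        # baseline prevalence near the reference temperature, used for the
        # odds-ratio -> risk-ratio conversion when summarising logit-style
        ref = self.crossbasis_spec.reference
        t = df[self.panel.exposure].to_numpy(dtype=float)[usable]
        band = np.abs(t - ref) <= 2.0
        p0 = float(np.nanmean(y[usable][band])) if band.any() else float(
            np.nanmean(y[usable])
        )
        return CaseTimeSeriesResults(self, res, design, strata, p0_reference=p0)


class CaseTimeSeriesResults:
    """Fitted case-time-series model: coefficients, covariance, curves."""

    def __init__(
        self,
        model: CaseTimeSeriesModel,
        fit: FitResult,
        design: DesignInfo,
        strata: StratumIndex,
        p0_reference: float,
    ) -> None:
        self.model = model
        self.fit = fit
        self.design = design
        self.strata = strata
        self.p0_reference = p0_reference

    # -- plumbing ---------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self.fit.params, index=self.fit.columns)

    @property
    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fit.cov_params, index=self.fit.columns, columns=self.fit.columns
        )

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.fit.cov_params)), index=self.fit.columns
        )

    @property
    def converged(self) -> bool:
        return self.fit.converged

    # -- exposure-response ------------------------------------------------
    def cumulative_curve(self, grid=None, allow_extrapolation: bool = False):
        from .curves import cumulative_curve

        return cumulative_curve(
            self.fit,
            self.model.crossbasis_spec,
            grid,
            allow_extrapolation=allow_extrapolation,
        )

    def rr_contrast(self, t_high: float, t_low: float):
        from .curves import rr_contrast

        spec = self.model.crossbasis_spec
        lo, hi = spec.exposure.boundary
        grid = np.union1d(
            np.linspace(lo, hi, 151), [spec.reference, t_high, t_low]
        )
        # contrast temperatures slightly beyond the fitted boundary use the
        # natural spline's linear tails
        curve = self.cumulative_curve(grid, allow_extrapolation=True)
        return rr_contrast(curve, t_high, t_low)

    def summary(self) -> str:
        f = self.fit
        spec = self.model.crossbasis_spec
        lines = [
            "Case-time-series conditional Poisson (absorbed strata)",
            f"  outcome: {self.model.outcome}   rows: {f.nobs}",
            f"  strata: {f.n_strata} informative "
            f"({f.n_dropped_strata} dropped, zero events)",
            f"  log-likelihood: {f.llf:.3f}   iterations: {f.n_iter}"
            f"   converged: {f.converged}",
            f"  cross-basis: {spec.exposure.n_columns} df x "
            f"{spec.max_lag + 1} lags, reference {spec.reference:.2f} degC",
            "",
            f"  {'term':<22}{'coef':>12}{'se':>12}",
        ]
        bse = np.sqrt(np.diag(f.cov_params))
        for name, b, s in zip(f.columns, f.params, bse):
            lines.append(f"  {name:<22}{b:>12.5f}{s:>12.5f}")
        return "\n".join(lines)


def fit_subgroup(
    panel: NightlyPanel,
    grouping: str | Mapping[int, object],
    outcome: str = "osa",
    min_users: int = 10,
    **model_kwargs,
) -> dict:
    """Independent case-time-series fits per subgroup of users.

    ``grouping`` is either a panel column (constant within user) or a
    mapping user_id -> group label.  Groups with fewer than ``min_users``
    users, or with no informative strata, are skipped with a logged reason;
    skipped groups appear in the returned dict as None.
    """
    df = panel.data
    if isinstance(grouping, str):
        labels = df[grouping]
    else:
        labels = df["user_id"].map(grouping)
    groups = labels.dropna().unique()
    if len(groups) == 0:
        raise ValueError("grouping defines no groups")
    out: dict = {}
    for g in groups:
        sub = df[labels == g]
        n_users = sub["user_id"].nunique()
        if n_users < min_users:
            logger.warning("subgroup %r skipped: %d users < %d", g, n_users, min_users)
            out[g] = None
            continue
        sub_panel = NightlyPanel(
            sub.reset_index(drop=True), exposure=panel.exposure, max_lag=panel.max_lag
        )
        try:
            out[g] = CaseTimeSeriesModel(
                sub_panel, outcome=outcome, **model_kwargs
            ).fit()
        except ValueError as err:
            logger.warning("subgroup %r skipped: %s", g, err)
            out[g] = None
    return out
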