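"""Cumulative exposure-response curves and risk-ratio contrasts.

The association between temperature and nightly OSA is summarised by the
*cumulative* curve: the lag-specific log effects summed over the lag window
(0-4 days by default), anchored at a reference temperature where the log RR
is identically zero.  With the indicator lag basis this sum is an exact
column-group sum of the cross-basis coefficients.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import CrossBasisSpec, spline_evaluator

Z95 = 1.959964  # fixed 95% normal quantile

__all__ = [
    "ExposureResponseCurve",
    "RRContrast",
    "cumulative_curve",
    "rr_contrast",
    "odds_to_risk_ratio",
]


@dataclass
class ExposureResponseCurve:
    """Cumulative log-RR over a temperature grid, relative to a reference.

    ``var`` holds the pointwise variance of the cumulative log RR; ``cov``
    (optional, present for curves built from a fit in-session) the full
    covariance across grid points, needed for contrasts between two
    non-reference temperatures.  Curves round-trip through a CSV schema
    (grid, log_rr, var) with the reference and provenance in comment lines;
    the covariance is not serialised.
    """

    grid: np.ndarray
    log_rr: np.ndarray
    var: np.ndarray
    reference: float
    provenance: str = "external"
    cov: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.log_rr = np.asarray(self.log_rr, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if not (len(self.grid) == len(self.log_rr) == len(self.var)):
            raise ValueError("grid, log_rr and var must have equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if (self.var < -1e-12).any():
            raise ValueError("variances must be non-negative")

    # -- evaluation -------------------------------------------------------
    def _check_range(self, t: np.ndarray, clip: bool) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        lo, hi = self.grid[0], self.grid[-1]
        if clip:
            return np.clip(t, lo, hi)
        if np.any((t < lo) | (t > hi)):
            raise ValueError(
                f"temperature outside curve grid [{lo:.2f}, {hi:.2f}]; "
                "pass clip=True for flat extrapolation"
            )
        return t

    def log_rr_at(self, t, clip: bool = False) -> np.ndarray:
        t = self._check_range(t, clip)
        return np.interp(t, self.grid, self.log_rr)

    def rr_at(self, t, level: str = "mean", clip: bool = False) -> np.ndarray:
        """RR(t), interpolated on the RR scale; ``level`` picks the point
        estimate or the 95% CI envelope ('lower'/'upper')."""
        t = self._check_range(t, clip)
        shift = {"lower": -Z95, "mean": 0.0, "upper": Z95}[level]
        rr_grid = np.exp(self.log_rr + shift * np.sqrt(np.maximum(self.var, 0)))
        return np.interp(t, self.grid, rr_grid)

    def var_at(self, t, clip: bool = False) -> np.ndarray:
        t = self._check_range(t, clip)
        return np.interp(t, self.grid, self.var)

    # -- serialisation ----------------------------------------------------
    def to_csv(self, path) -> None:
        header = (
            f"# heatosa-curve reference={self.reference!r} "
            f"provenance={self.provenance!r}\n"
        )
        body = pd.DataFrame(
            {"temperature": self.grid, "log_rr": self.log_rr, "var": self.var}
        ).to_csv(index=False)
        with open(path, "w") as fh:
            fh.write(header + body)

    @classmethod
    def from_csv(cls, path) -> "ExposureResponseCurve":
        with open(path) as fh:
            first = fh.readline()
            rest = fh.read()
        reference = None
        if first.startswith("# heatosa-curve"):
            for tok in first.split():
                if tok.startswith("reference="):
                    reference = float(tok.split("=", 1)[1])
        else:
            rest = first + rest
        df = pd.read_csv(io.StringIO(rest))
        if reference is None:
            idx = int(np.argmin(np.abs(df["log_rr"].to_numpy())))
            reference = float(df["temperature"].iloc[idx])
        return cls(
            grid=df["temperature"].to_numpy(),
            log_rr=df["log_rr"].to_numpy(),
            var=df["var"].to_numpy(),
            reference=reference,
            provenance="external",
        )


@dataclass
class RRContrast:
    """RR between two temperatures with its 95% CI."""

    rr: float
    ci_low: float
    ci_high: float
    t_high: float
    t_low: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rr <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")
        if min(self.rr, self.ci_low, self.ci_high) <= 0:
            raise ValueError("risk ratios must be positive")


def cumulative_curve(
    fit,
    spec: CrossBasisSpec,
    grid=None,
    allow_extrapolation: bool = False,
) -> ExposureResponseCurve:
    """Sum the lag-specific effects into the cumulative curve.

    At grid temperature t the cumulative log RR is
    ``sum_l sum_j beta_{j,l} (b_j(t) - b_j(ref))``; with the indicator lag
    basis this reduces to the summed-over-lags coefficient vector applied to
    the centered exposure basis.  Variances come from the quadratic form of
    each contrast vector with the fitted covariance.
    """
    if not spec.exposure.is_resolved or spec.reference is None:
        raise ValueError("cross-basis spec must be resolved (fitted) first")
    lo, hi = spec.exposure.boundary
    if grid is None:
        # the reference joins the grid so the anchor point is exact
        grid = np.union1d(np.linspace(lo, hi, 151), [spec.reference])
    grid = np.asarray(grid, dtype=float)
    if not allow_extrapolation and ((grid < lo - 1e-9) | (grid > hi + 1e-9)).any():
        raise ValueError(
            "grid extends beyond the exposure boundary knots; "
            "set allow_extrapolation=True to use the linear tails"
        )

    from dataclasses import replace

    exp_spec = replace(spec.exposure, center=float(spec.reference))
    fn = spline_evaluator(exp_spec)
    B = fn(grid)  # (n_grid, j), centered at the reference

    cb_idx = list(fit.crossbasis_columns)
    j = spec.exposure.n_columns
    n_lag = spec.max_lag + 1
    if len(cb_idx) != j * n_lag:
        raise ValueError("fit bookkeeping does not match the cross-basis spec")
    beta = np.asarray(fit.params)[cb_idx].reshape(n_lag, j)
    cov = np.asarray(fit.cov_params)[np.ix_(cb_idx, cb_idx)]

    beta_sum = beta.sum(axis=0)  # sum over lags
    log_rr = B @ beta_sum
    # contrast matrix: grid point g has contrast vector tile(B[g], n_lag)
    C = np.tile(B, (1, n_lag))  # (n_grid, j*n_lag) ordered lag-major
    # reorder to match cb column order (j within lag): already lag-major ✓
    curve_cov = C @ cov @ C.T
    var = np.maximum(np.diag(curve_cov), 0.0)
    return ExposureResponseCurve(
        grid=grid,
        log_rr=log_rr,
        var=var,
        reference=float(spec.reference),
        provenance="fit",
        cov=curve_cov,
    )


def rr_contrast(curve: ExposureResponseCurve, t_high: float, t_low: float) -> RRContrast:
    """RR(t_high vs t_low) with a delta-method CI on the log scale.

    Uses the full grid covariance when the curve carries one; otherwise the
    contrast must involve the reference temperature (whose variance is
    zero), because pointwise variances alone cannot give the covariance of
    a difference.
    """
    d = float(curve.log_rr_at(t_high) - curve.log_rr_at(t_low))
    if t_high == t_low:
        rr = 1.0
        return RRContrast(rr, rr, rr, t_high, t_low)

    def weights(t):
        w = np.zeros(len(curve.grid))
        i = int(np.searchsorted(curve.grid, t, side="right") - 1)
        i = min(max(i, 0), len(curve.grid) - 2)
        g0, g1 = curve.grid[i], curve.grid[i + 1]
        frac = (t - g0) / (g1 - g0)
        w[i], w[i + 1] = 1 - frac, frac
        return w

    if curve.cov is not None:
        u = weights(t_high) - weights(t_low)
        var = float(u @ curve.cov @ u)
    elif np.isclose(t_low, curve.reference):
        var = float(curve.var_at(t_high))
    elif np.isclose(t_high, curve.reference):
        var = float(curve.var_at(t_low))
    else:
        raise ValueError(
            "curve has no covariance; only contrasts against the reference "
            "temperature are available"
        )
    se = np.sqrt(max(var, 0.0))
    rr = float(np.exp(d))
    return RRContrast(
        rr=rr,
        ci_low=float(np.exp(d - Z95 * se)),
        ci_high=float(np.exp(d + Z95 * se)),
        t_high=t_high,
        t_low=t_low,
    )


def odds_to_risk_ratio(or_value, p0: float):
    """Convert an odds ratio to a risk ratio at baseline risk ``p0``:
    RR = OR / (1 - p0 + p0 * OR).  Applied element-wise, so CI bounds can
    be converted alongside the point estimate."""
    or_value = np.asarray(or_value, dtype=float)
    if (or_value <= 0).any():
        raise ValueError("odds ratios must be positive")
    if not 0 <= p0 < 1:
        raise ValueError("baseline risk must be in [0, 1)")
    out = or_value / (1 - p0 + p0 * or_value)
    return float(out) if out.ndim == 0 else out
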