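"""Natural cubic spline bases and the exposure x lag cross-basis.

The distributed-lag non-linear model (DLNM) used throughout this package
represents the temperature-response as a natural cubic spline and the lag
structure as one indicator per lag day.  The tensor product of the two —
the *cross-basis* — is the design block whose coefficients encode the
lag-specific log rate ratios; summing over lags gives the cumulative
exposure-response curve.

The spline basis follows the classical natural-spline construction: a cubic
B-spline basis on the given knots, constrained to have zero second
derivative at the boundary knots and extended linearly beyond them.  The
constant function is removed from the span (models here absorb intercepts
into strata), so a basis with ``k`` internal knots has ``k + 1`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineSpec",
    "CrossBasisSpec",
    "BasisMatrix",
    "natural_spline_basis",
    "lagged_exposure_matrix",
    "cross_basis",
]


@dataclass(frozen=True)
class SplineSpec:
    """Specification of a natural cubic spline basis.

    Exactly one of ``df`` / ``knots`` drives knot placement: with ``df``,
    internal knots sit at equally spaced quantiles of the data the spec is
    resolved against (df=4 gives the 25th/50th/75th percentiles); with
    explicit ``knots`` the df equals ``len(knots) + 1``.  ``boundary``
    defaults to the data min/max.  ``center``, if set, subtracts the basis
    row at that value so every column vanishes there.
    """

    df: int | None = 4
    knots: tuple[float, ...] | None = None
    boundary: tuple[float, float] | None = None
    center: float | None = None

    def __post_init__(self) -> None:
        if self.knots is None and (self.df is None or self.df < 1):
            raise ValueError("need df >= 1 or explicit knots")
        if self.knots is not None:
            k = tuple(float(v) for v in self.knots)
            if any(not np.isfinite(v) for v in k):
                raise ValueError("non-finite knots")
            if list(k) != sorted(set(k)):
                raise ValueError("knots must be strictly increasing")
            object.__setattr__(self, "knots", k)
        if self.boundary is not None:
            lo, hi = (float(v) for v in self.boundary)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("boundary knots must be finite and increasing")
            if self.knots and (self.knots[0] <= lo or self.knots[-1] >= hi):
                raise ValueError("internal knots must lie strictly inside boundary")
            object.__setattr__(self, "boundary", (lo, hi))

    @property
    def n_columns(self) -> int:
        if self.knots is not None:
            return len(self.knots) + 1
        return int(self.df)

    def resolve(self, x: np.ndarray) -> "SplineSpec":
        """Fill in knots/boundary from data quantiles; idempotent."""
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        boundary = self.boundary
        if boundary is None:
            boundary = (float(x.min()), float(x.max()))
        knots = self.knots
        if knots is None:
            n_internal = int(self.df) - 1
            if n_internal > 0:
                probs = np.linspace(0, 1, n_internal + 2)[1:-1]
                q = np.quantile(x, probs)
                knots = tuple(float(v) for v in q)
                if list(knots) != sorted(set(knots)) or (
                    knots[0] <= boundary[0] or knots[-1] >= boundary[1]
                ):
                    raise ValueError(
                        "too few distinct values to place the requested knots"
                    )
            else:
                knots = ()
        return replace(self, df=len(knots) + 1, knots=knots, boundary=boundary)

    @property
    def is_resolved(self) -> bool:
        return self.knots is not None and self.boundary is not None


@dataclass(frozen=True)
class CrossBasisSpec:
    """Exposure spline x lag-indicator cross-basis specification."""

    exposure: SplineSpec = field(default_factory=SplineSpec)
    max_lag: int = 4
    reference: float | None = None  # None -> 25th percentile of fitting data

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")

    @property
    def n_columns(self) -> int:
        return self.exposure.n_columns * (self.max_lag + 1)

    def resolve(self, x: np.ndarray) -> "CrossBasisSpec":
        exposure = self.exposure.resolve(np.asarray(x, dtype=float))
        ref = self.reference
        if ref is None:
            vals = np.asarray(x, dtype=float)
            ref = float(np.quantile(vals[np.isfinite(vals)], 0.25))
        return replace(self, exposure=exposure, reference=ref)


@dataclass
class BasisMatrix:
    """A design block: values plus column labels.

    For a cross-basis the labels are ``(exposure-basis index, lag)`` pairs;
    for a plain spline basis they are the basis-function indices.
    """

    values: np.ndarray
    labels: list
    spec: object | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


class _NaturalSplineBasis:
    """Callable natural-spline basis on fixed knots (no intercept column)."""

    def __init__(self, knots: Sequence[float], boundary: tuple[float, float]):
        a, b = boundary
        t = np.r_[[a] * 4, list(knots), [b] * 4]
        n_b = len(knots) + 4
        self._bspl = BSpline(t, np.eye(n_b), 3, extrapolate=False)
        # natural constraint: zero curvature at both boundary knots; the
        # first B-spline is dropped to remove the constant from the span
        const = self._bspl.derivative(2)(np.array([a, b]))[:, 1:]
        q = np.linalg.qr(const.T, mode="complete")[0]
        self._proj = q[:, 2:]
        self._a, self._b = a, b
        self.n_columns = n_b - 3

    def _inside(self, pts: np.ndarray, nu: int = 0) -> np.ndarray:
        f = self._bspl if nu == 0 else self._bspl.derivative(nu)
        return f(pts)[:, 1:] @ self._proj

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.empty((x.size, self.n_columns))
        flat = x.ravel()
        inside = (flat >= self._a) & (flat <= self._b)
        if inside.any():
            out[inside] = self._inside(flat[inside])
        for bound, mask in ((self._a, flat < self._a), (self._b, flat > self._b)):
            if mask.any():  # linear extension beyond the boundary knots
                v = self._inside(np.array([bound]))
                d = self._inside(np.array([bound]), nu=1)
                out[mask] = v + (flat[mask] - bound)[:, None] * d
        return out


def natural_spline_basis(
    x: np.ndarray, spec: SplineSpec, *, return_matrix: bool = True
) -> BasisMatrix | np.ndarray:
    """Evaluate a natural cubic spline basis at ``x``.

    The basis is piecewise cubic, twice continuously differentiable inside
    the boundary knots and linear beyond them.  When ``spec.center`` is set
    the row evaluated at the centering value is subtracted, so all columns
    vanish there.
    """
    x = np.asarray(x, dtype=float)
    spec = spec.resolve(x) if not spec.is_resolved else spec
    fn = _NaturalSplineBasis(spec.knots, spec.boundary)
    vals = fn(x)
    if spec.center is not None:
        vals = vals - fn(np.array([float(spec.center)]))
    if not return_matrix:
        return vals
    return BasisMatrix(vals, labels=list(range(fn.n_columns)), spec=spec)


def spline_evaluator(spec: SplineSpec):
    """Return f(t) -> basis rows for a resolved spec (centering applied)."""
    if not spec.is_resolved:
        raise ValueError("spec must be resolved against data first")
    fn = _NaturalSplineBasis(spec.knots, spec.boundary)
    if spec.center is None:
        return fn

    center_row = fn(np.array([float(spec.center)]))

    def centered(x: np.ndarray) -> np.ndarray:
        return fn(np.asarray(x, dtype=float)) - center_row

    return centered


def lagged_exposure_matrix(
    series: np.ndarray, max_lag: int
) -> tuple[np.ndarray, np.ndarray]:
    """Lag matrix for one contiguous daily series.

    Returns ``(L, complete)`` where column ``l`` of ``L`` holds the exposure
    ``l`` days before each entry and ``complete`` flags rows with a full lag
    window (the first ``max_lag`` rows are incomplete and padded with NaN).
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    out = np.full((n, max_lag + 1), np.nan)
    for lag in range(max_lag + 1):
        out[lag:, lag] = series[: n - lag] if lag else series
    complete = np.ones(n, dtype=bool)
    complete[:max_lag] = False
    return out, complete


def cross_basis(lagged: np.ndarray, spec: CrossBasisSpec) -> BasisMatrix:
    """Tensor-product basis: exposure spline per lag, indicator lag basis.

    Column ``(j, l)`` is exposure-basis function ``j`` evaluated at the
    lag-``l`` exposure, centered at the reference temperature so that a row
    of exposures all equal to the reference maps to the zero vector.
    Columns are ordered lag-major: ``(0,0) .. (J-1,0), (0,1) ..``.
    """
    lagged = np.asarray(lagged, dtype=float)
    if lagged.ndim != 2 or lagged.shape[1] != spec.max_lag + 1:
        raise ValueError(
            f"lag matrix must have {spec.max_lag + 1} columns, got {lagged.shape}"
        )
    if not spec.exposure.is_resolved or spec.reference is None:
        spec = spec.resolve(lagged[np.isfinite(lagged[:, 0]), 0])
    exp_spec = replace(spec.exposure, center=float(spec.reference))
    fn = spline_evaluator(exp_spec)
    n, n_lag = lagged.shape
    j = exp_spec.n_columns
    out = np.empty((n, j * n_lag))
    labels = []
    for lag in range(n_lag):
        out[:, lag * j : (lag + 1) * j] = fn(lagged[:, lag])
        labels.extend((jj, lag) for jj in range(j))
    return BasisMatrix(out, labels=labels, spec=spec)
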