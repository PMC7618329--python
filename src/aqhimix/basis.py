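"""Spline bases, moving averages and spline imputation.

Natural cubic splines follow the classic truncated-power construction with
natural (linear-beyond-boundary) constraints, matching R's ``splines::ns``
parameterization up to an invertible linear map: for knots
xi_1 < ... < xi_K (internal plus the two boundaries) the basis is
``x, d_1 - d_{K-1}, ..., d_{K-2} - d_{K-1}`` where

    d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k).

Each column has zero second and third derivatives outside the boundary
knots, so the fitted curve is linear there. With M internal knots and no
intercept column the basis has M + 1 columns.

I-splines (monotone basis) are built as reverse cumulative sums of a
clamped cubic B-spline basis; each column is nondecreasing from 0 to 1,
so any nonnegative coefficient combination is a nondecreasing function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .errors import (
    DegenerateBasisError,
    InvalidKnotsError,
    InvalidParameterError,
    UnimputableError,
)

__all__ = [
    "SplineBasis",
    "natural_cubic_basis",
    "ns_basis_from_df",
    "moving_average",
    "ispline_basis",
    "impute_pollutant_spline",
]


@dataclass(frozen=True)
class SplineBasis:
    """Metadata for a natural cubic spline basis.

    Attributes
    ----------
    knot_positions : internal knots, strictly increasing, on the exposure scale.
    boundary_knots : (lower, upper) pair enclosing the internal knots.
    intercept_flag : whether a constant column is part of the basis.
    """

    knot_positions: tuple[float, ...]
    boundary_knots: tuple[float, float]
    intercept_flag: bool = False

    def __post_init__(self) -> None:
        kp = np.asarray(self.knot_positions, dtype=float)
        lo, hi = self.boundary_knots
        if kp.size and np.any(np.diff(kp) <= 0):
            raise InvalidKnotsError("internal knots must be strictly increasing")
        if not lo < hi:
            raise InvalidKnotsError("boundary knots must satisfy lower < upper")
        if kp.size and (kp[0] <= lo or kp[-1] >= hi):
            raise InvalidKnotsError("boundary knots must strictly enclose internal knots")

    @property
    def n_basis(self) -> int:
        return len(self.knot_positions) + 1 + int(self.intercept_flag)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        b = natural_cubic_basis(x, np.asarray(self.knot_positions), self.boundary_knots)
        if self.intercept_flag:
            b = np.column_stack([np.ones(len(b)), b])
        return b


def natural_cubic_basis(
    x: np.ndarray,
    internal_knots: np.ndarray,
    boundary_knots: tuple[float, float],
) -> np.ndarray:
    """Natural cubic spline basis without an intercept column.

    Parameters
    ----------
    x : evaluation points (finite; values beyond the boundary knots are
        extrapolated linearly, per the natural constraint).
    internal_knots : strictly increasing knots inside the boundary.
    boundary_knots : (lower, upper).

    Returns
    -------
    (len(x), len(internal_knots) + 1) array.
    """
    x = np.asarray(x, dtype=float)
    internal_knots = np.asarray(internal_knots, dtype=float)
    lo, hi = float(boundary_knots[0]), float(boundary_knots[1])
    # delegate validation
    SplineBasis(tuple(internal_knots), (lo, hi))
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("x must be finite")

    # evaluate on boundary-normalised coordinates: identical span (natural
    # splines are affine-equivariant) but O(1) columns, so downstream
    # regressions stay well conditioned even when x is a long day index
    span = hi - lo
    x = (x - lo) / span
    knots = np.concatenate([[0.0], (internal_knots - lo) / span, [1.0]])
    K = len(knots)
    cols = [x]
    if K > 2:
        def d(k: int) -> np.ndarray:
            return (
                np.clip(x - knots[k], 0, None) ** 3
                - np.clip(x - knots[K - 1], 0, None) ** 3
            ) / (knots[K - 1] - knots[k])

        d_last = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - d_last)
    return np.column_stack(cols)


def ns_basis_from_df(x: np.ndarray, df: int, intercept: bool = False) -> np.ndarray:
    """Natural cubic basis with ``df`` columns, knots at quantiles of ``x``.

    Internal knots are placed at ``df - 1`` equally spaced interior
    quantiles (the ``splines::ns`` convention); boundaries at min/max.
    """
    x = np.asarray(x, dtype=float)
    obs = x[np.isfinite(x)]
    if obs.size < 2 or np.ptp(obs) == 0:
        raise DegenerateBasisError("need at least two distinct finite values")
    n_internal = df - 1 - int(intercept)
    if n_internal < 0:
        raise InvalidParameterError(f"df={df} too small")
    probs = np.linspace(0, 1, n_internal + 2)[1:-1]
    internal = np.unique(np.quantile(obs, probs)) if n_internal else np.array([])
    lo, hi = float(obs.min()), float(obs.max())
    # quantile ties collapse knots; nudge off the boundary if needed
    internal = internal[(internal > lo) & (internal < hi)]
    b = natural_cubic_basis(x, internal, (lo, hi))
    if intercept:
        b = np.column_stack([np.ones(len(b)), b])
    return b


def moving_average(
    series: np.ndarray, window: int, include_current: bool = True
) -> np.ndarray:
    """Trailing moving average; missingness propagates.

    The value at day ``t`` is the mean of days ``t-window+1 .. t``
    (or ``t-window .. t-1`` when ``include_current`` is False); it is NaN
    whenever any constituent day is missing or out of range, mirroring the
    exclude-missing-days analysis rule rather than renormalizing.
    """
    if window < 1:
        raise InvalidParameterError("window must be >= 1")
    x = np.asarray(series, dtype=float)
    n = x.size
    out = np.full(n, np.nan)
    if n == 0:
        return out
    shift = 0 if include_current else 1
    stacked = np.full((window, n), np.nan)
    for j in range(window):
        lag = j + shift
        if lag < n:
            stacked[j, lag:] = x[: n - lag]
    out = stacked.mean(axis=0)  # NaN if any constituent NaN
    return out


def ispline_basis(
    x: np.ndarray,
    interior_knots: np.ndarray,
    boundary: tuple[float, float],
    degree: int = 3,
) -> np.ndarray:
    """Monotone (I-spline) basis: each column nondecreasing from 0 to 1.

    Built as reverse cumulative sums of a clamped B-spline basis of the
    given degree; the constant leading column is dropped (an intercept
    belongs to the unconstrained part of a design). Evaluation is clipped
    to the boundary, so columns extend flat outside it.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(boundary[0]), float(boundary[1])
    if not lo < hi:
        raise InvalidKnotsError("degenerate boundary")
    interior = np.asarray(interior_knots, dtype=float)
    interior = interior[(interior > lo) & (interior < hi)]
    t = np.concatenate([[lo] * (degree + 1), np.sort(interior), [hi] * (degree + 1)])
    n_b = len(t) - degree - 1
    xc = np.clip(x, lo, hi)
    design = BSpline.design_matrix(xc, t, degree, extrapolate=False).toarray()
    # cumulative sum from the right: I_j = sum_{m >= j} B_m, drop I_0 == 1
    isp = np.cumsum(design[:, ::-1], axis=1)[:, ::-1]
    return isp[:, 1:n_b]


def impute_pollutant_spline(series: np.ndarray, df_per_year: int = 7) -> np.ndarray:
    """Fill gaps with a natural-cubic-spline-of-time fit to observed days.

    Observed entries pass through unchanged; predictions are floored at 0
    (concentrations are nonnegative).
    """
    if df_per_year < 1:
        raise InvalidParameterError("df_per_year must be >= 1")
    x = np.asarray(series, dtype=float)
    obs = np.isfinite(x)
    if obs.sum() < 2:
        raise UnimputableError("need at least 2 observed values")
    if obs.all():
        return x.copy()
    t = np.arange(x.size, dtype=float)
    df = max(3, int(round(df_per_year * x.size / 365.25)))
    df = min(df, max(3, obs.sum() - 1))
    t_obs = t[obs]
    n_internal = df - 1
    probs = np.linspace(0, 1, n_internal + 2)[1:-1]
    internal = np.unique(np.quantile(t_obs, probs))
    lo, hi = t.min() - 0.5, t.max() + 0.5
    basis = np.column_stack(
        [np.ones(x.size), natural_cubic_basis(t, internal, (lo, hi))]
    )
    coef, *_ = np.linalg.lstsq(basis[obs], x[obs], rcond=None)
    out = x.copy()
    out[~obs] = np.clip(basis[~obs] @ coef, 0.0, None)
    return out
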