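"""DLNM cross-basis: tensor product of exposure and lag spline bases.

For exposure series x_t and maximum lag L, the lag matrix Q has rows
(x_t, x_{t-1}, ..., x_{t-L}). With an exposure-dimension basis f (v_df
columns) and a lag-dimension basis C evaluated at lags 0..L ((L+1) x l_df),
the cross-basis column (j, l) at day t is sum_u f_j(x_{t-u}) C[u, l].
A row is missing whenever any lagged exposure it needs is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import SplineBasis, natural_cubic_basis
from .errors import DegenerateBasisError, InvalidParameterError

__all__ = ["CrossBasis", "build_cross_basis", "lag_matrix"]


@dataclass
class CrossBasis:
    matrix: np.ndarray                    # n_days x (v_df * l_df), NaN rows where unresolved
    max_lag: int
    var_type: str                         # "ns" or "linear"
    lag_type: str                         # "ns", "indicator" or "constant"
    var_basis: SplineBasis | None
    lag_design: np.ndarray = field(repr=False)  # (max_lag+1) x l_df

    @property
    def v_df(self) -> int:
        return 1 if self.var_type == "linear" else self.var_basis.n_basis

    @property
    def l_df(self) -> int:
        return self.lag_design.shape[1]

    def exposure_design(self, x: np.ndarray) -> np.ndarray:
        """Exposure-dimension basis evaluated at concentrations ``x``."""
        x = np.asarray(x, dtype=float)
        if self.var_type == "linear":
            return x[:, None]
        return self.var_basis.evaluate(x)


def lag_matrix(exposure: np.ndarray, max_lag: int) -> np.ndarray:
    """(n, max_lag+1) matrix of lagged copies; out-of-range entries NaN."""
    x = np.asarray(exposure, dtype=float)
    n = x.size
    q = np.full((n, max_lag + 1), np.nan)
    for lag in range(max_lag + 1):
        q[lag:, lag] = x[: n - lag] if lag else x
    return q


def _lag_basis(max_lag: int, lag_type: str, n_internal: int) -> np.ndarray:
    lags = np.arange(max_lag + 1, dtype=float)
    if lag_type == "indicator":
        return np.eye(max_lag + 1)
    if lag_type == "constant":          # summed-lag basis: one flat column
        return np.ones((max_lag + 1, 1))
    if lag_type != "ns":
        raise InvalidParameterError(f"unknown lag basis type {lag_type!r}")
    if max_lag == 0:
        return np.ones((1, 1))
    # natural cubic spline on log(lag + 1); internal knots equally spaced
    # between log(1)=0 and log(max_lag+1); intercept included
    loglag = np.log(lags + 1.0)
    lo, hi = loglag[0], loglag[-1]
    internal = np.linspace(lo, hi, n_internal + 2)[1:-1] if n_internal else np.array([])
    b = natural_cubic_basis(loglag, internal, (lo - 1e-9, hi + 1e-9))
    return np.column_stack([np.ones(len(lags)), b])


def build_cross_basis(
    exposure: np.ndarray,
    max_lag: int = 7,
    var_knot_quantiles: tuple[float, float] = (0.25, 0.75),
    lag_internal_knots: int = 2,
    var_type: str = "ns",
    lag_type: str = "ns",
) -> CrossBasis:
    """Build the DLNM design for one exposure series.

    The exposure basis is a natural cubic spline with internal knots at the
    series' observed concentration quantiles (default 25th/75th) or, with
    ``var_type='linear'``, the identity. The lag basis is a natural cubic
    spline of log(lag+1) with an intercept (default), or per-lag
    indicators. Defaults give v_df=3, l_df=4, 12 columns.
    """
    x = np.asarray(exposure, dtype=float)
    if max_lag < 0:
        raise InvalidParameterError("max_lag must be >= 0")
    if x.size <= max_lag:
        raise InvalidParameterError("exposure shorter than max_lag")
    obs = x[np.isfinite(x)]
    if obs.size < 2 or np.ptp(obs) == 0:
        raise DegenerateBasisError("constant or empty exposure series")

    var_basis = None
    if var_type == "ns":
        internal = np.unique(np.quantile(obs, var_knot_quantiles))
        lo, hi = float(obs.min()), float(obs.max())
        internal = internal[(internal > lo) & (internal < hi)]
        var_basis = SplineBasis(tuple(internal), (lo, hi))
    elif var_type != "linear":
        raise InvalidParameterError(f"unknown var basis type {var_type!r}")

    lag_design = _lag_basis(max_lag, lag_type, lag_internal_knots)
    q = lag_matrix(x, max_lag)
    bad = ~np.all(np.isfinite(q), axis=1)
    q_safe = np.where(np.isfinite(q), q, 0.0)

    v_df = 1 if var_type == "linear" else var_basis.n_basis
    l_df = lag_design.shape[1]
    n = x.size
    mat = np.empty((n, v_df * l_df))
    for j in range(v_df):
        if var_type == "linear":
            r = q_safe
        else:
            flat = var_basis.evaluate(q_safe.ravel())[:, j]
            r = flat.reshape(q.shape)
        mat[:, j * l_df : (j + 1) * l_df] = r @ lag_design
    mat[bad] = np.nan
    return CrossBasis(
        matrix=mat,
        max_lag=max_lag,
        var_type=var_type,
        lag_type=lag_type,
        var_basis=var_basis,
        lag_design=lag_design,
    )
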