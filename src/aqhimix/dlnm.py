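"""First-stage single-pollutant city models.

Each city/pollutant model is a quasi-Poisson regression of daily deaths on
a DLNM cross-basis (lags 0-7) plus the shared confounder block: a natural
cubic spline of time (7 df per year), day-of-week indicators, and natural
cubic splines of the 8-day moving averages of temperature (6 df) and
relative humidity (3 df). A companion linear model on the 3-day (lag 0-2)
moving average supplies the scalar per-ug/m3 log relative risk feeding the
single-pollutant death risk function.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .basis import moving_average, ns_basis_from_df
from .crossbasis import CrossBasis, build_cross_basis
from .data import CityDailySeries
from .errors import DataTooSparseError, DegenerateBasisError
from .glm import GLMFit, fit_quasipoisson

__all__ = [
    "ModelConfig",
    "CityCurveFit",
    "confounder_design",
    "fit_city_dlnm",
    "linear_beta_city",
    "cumulative_exposure_response",
    "lag_response",
]


@dataclass(frozen=True)
class ModelConfig:
    """Specification shared by all first-stage regressions.

    Defaults mirror the headline analysis; the alternates exercised in
    sensitivity analyses (time df 5-9/yr, temperature df 3-7, 3- or 21-day
    weather windows, humidity on/off) are plain field overrides.
    """

    max_lag: int = 7
    exposure_ma_window: int = 3        # lag 0-2 moving average
    time_df_per_year: float = 7.0
    temp_df: int = 6
    rh_df: int = 3
    weather_ma_window: int = 8
    adjust_humidity: bool = True
    adjust_holiday: bool = False
    var_knot_quantiles: tuple[float, float] = (0.25, 0.75)
    lag_internal_knots: int = 2
    min_rows_per_column: int = 10

    def with_(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


@dataclass
class CityCurveFit:
    """Cross-basis block of a fitted city DLNM."""

    city_id: str
    pollutant_id: str
    crossbasis_coefs: np.ndarray
    crossbasis_vcov: np.ndarray
    crossbasis: CrossBasis
    concentration_range: tuple[float, float]
    dispersion: float
    n_obs: int


def confounder_design(series: CityDailySeries, config: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Intercept + time spline + day-of-week + weather splines.

    Returns (design, complete_row_mask). Rows where a weather moving
    average is unresolved are masked out rather than imputed.
    """
    n = len(series)
    t = np.arange(n, dtype=float)
    time_df = max(3, int(round(config.time_df_per_year * series.n_years)))
    time_spline = ns_basis_from_df(t, time_df)

    dow = series.dates.dayofweek.to_numpy()
    dow_dummies = np.column_stack([(dow == d).astype(float) for d in range(1, 7)])

    temp_ma = moving_average(series.temperature, config.weather_ma_window)
    blocks = [np.ones((n, 1)), time_spline, dow_dummies]
    if config.adjust_holiday:
        # fixed-date public holidays (sensitivity adjustment)
        md = list(zip(series.dates.month, series.dates.day))
        holidays = {(1, 1), (5, 1), (12, 25), (12, 26)}
        blocks.append(np.array([[1.0] if x in holidays else [0.0] for x in md]))
    mask = np.isfinite(temp_ma)
    rh_ma = None
    if config.adjust_humidity:
        rh_ma = moving_average(series.humidity, config.weather_ma_window)
        mask &= np.isfinite(rh_ma)

    temp_b = np.full((n, config.temp_df), np.nan)
    temp_b[mask] = ns_basis_from_df(temp_ma[mask], config.temp_df)
    blocks.append(temp_b)
    if config.adjust_humidity:
        rh_b = np.full((n, config.rh_df), np.nan)
        rh_b[mask] = ns_basis_from_df(rh_ma[mask], config.rh_df)
        blocks.append(rh_b)
    design = np.column_stack(blocks)
    return design, mask


def _assemble_and_fit(
    series: CityDailySeries,
    exposure_block: np.ndarray,
    config: ModelConfig,
) -> tuple[GLMFit, int, np.ndarray]:
    conf, mask = confounder_design(series, config)
    mask = mask & np.all(np.isfinite(exposure_block), axis=1) & np.isfinite(series.deaths)
    design = np.column_stack([exposure_block, conf])
    p = design.shape[1]
    if mask.sum() < p * config.min_rows_per_column:
        raise DataTooSparseError(
            f"{mask.sum()} complete days for {p} columns "
            f"(need {p * config.min_rows_per_column})"
        )
    fit = fit_quasipoisson(series.deaths[mask], design[mask])
    return fit, exposure_block.shape[1], mask


def fit_city_dlnm(
    series: CityDailySeries, pollutant_id: str, config: ModelConfig | None = None
) -> CityCurveFit:
    """Quasi-Poisson DLNM for one city and pollutant.

    Returns the cross-basis block of coefficients and covariance; the
    confounder block is profiled out of downstream summaries.
    """
    config = config or ModelConfig()
    x = series.pollutant(pollutant_id)
    obs = x[np.isfinite(x)]
    if obs.size < 2 or np.ptp(obs) == 0:
        raise DegenerateBasisError(f"{pollutant_id} is constant in {series.city_id}")
    cb = build_cross_basis(
        x,
        max_lag=config.max_lag,
        var_knot_quantiles=config.var_knot_quantiles,
        lag_internal_knots=config.lag_internal_knots,
    )
    fit, k, _ = _assemble_and_fit(series, cb.matrix, config)
    return CityCurveFit(
        city_id=series.city_id,
        pollutant_id=pollutant_id,
        crossbasis_coefs=fit.coefficients[:k],
        crossbasis_vcov=fit.covariance[:k, :k],
        crossbasis=cb,
        concentration_range=(float(obs.min()), float(obs.max())),
        dispersion=fit.dispersion,
        n_obs=fit.n_obs,
    )


def linear_beta_city(
    series: CityDailySeries, pollutant_id: str, config: ModelConfig | None = None
) -> tuple[float, float]:
    """Scalar log-RR per ug/m3 of the lag 0-2 moving-average exposure.

    Same confounders as the DLNM, with the cross-basis replaced by one
    linear term; this is the per-pollutant coefficient entering the
    single-pollutant death risk function.
    """
    config = config or ModelConfig()
    x = series.pollutant(pollutant_id)
    obs = x[np.isfinite(x)]
    if obs.size < 2 or np.ptp(obs) == 0:
        raise DegenerateBasisError(f"{pollutant_id} is constant in {series.city_id}")
    ma = moving_average(x, config.exposure_ma_window)
    fit, _, _ = _assemble_and_fit(series, ma[:, None], config)
    return float(fit.coefficients[0]), float(fit.covariance[0, 0])


def _curve_contrast(fit: CityCurveFit, conc: np.ndarray, reference: float) -> np.ndarray:
    """Rows of the cumulative (lag-summed) basis contrast vs the reference."""
    cb = fit.crossbasis
    lag_weights = cb.lag_design.sum(axis=0)          # length l_df
    vb = cb.exposure_design(np.asarray(conc, dtype=float))
    vb_ref = cb.exposure_design(np.array([reference]))
    diff = vb - vb_ref                                # n x v_df
    # kron ordering matches cross-basis columns (var-major, lag-minor)
    return np.column_stack(
        [diff[:, j, None] * lag_weights[None, :] for j in range(diff.shape[1])]
    ).reshape(len(conc), -1)


def cumulative_exposure_response(
    fit: CityCurveFit,
    grid: np.ndarray,
    reference: float = 0.0,
    alpha: float = 0.05,
) -> dict[str, np.ndarray]:
    """Percent change in mortality (with CI) along a concentration grid.

    Cumulates the lag dimension; the curve is exactly 0% at the reference.
    References outside the observed range are permitted (the natural basis
    extrapolates linearly) but flagged.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = fit.concentration_range
    extrapolated = reference < lo or reference > hi
    contrast = _curve_contrast(fit, grid, reference)
    log_rr = contrast @ fit.crossbasis_coefs
    var = np.einsum("ij,jk,ik->i", contrast, fit.crossbasis_vcov, contrast)
    se = np.sqrt(np.clip(var, 0, None))
    z = stats.norm.ppf(1 - alpha / 2)
    return {
        "grid": grid,
        "percent": 100.0 * np.expm1(log_rr),
        "lo": 100.0 * np.expm1(log_rr - z * se),
        "hi": 100.0 * np.expm1(log_rr + z * se),
        "log_rr": log_rr,
        "se": se,
        "extrapolated_reference": extrapolated,
    }


def lag_response(
    fit: CityCurveFit,
    at_concentration: float,
    reference: float = 0.0,
    alpha: float = 0.05,
) -> dict[str, np.ndarray]:
    """Per-lag percent change at one concentration contrast.

    The per-lag log-RRs sum to the cumulative log-RR at the same contrast.
    """
    cb = fit.crossbasis
    vb = cb.exposure_design(np.array([at_concentration]))
    vb_ref = cb.exposure_design(np.array([reference]))
    diff = (vb - vb_ref)[0]                           # v_df
    lags = np.arange(cb.max_lag + 1)
    rows = np.column_stack(
        [diff[j] * cb.lag_design for j in range(diff.size)]
    ).reshape(len(lags), -1)
    log_rr = rows @ fit.crossbasis_coefs
    var = np.einsum("ij,jk,ik->i", rows, fit.crossbasis_vcov, rows)
    se = np.sqrt(np.clip(var, 0, None))
    z = stats.norm.ppf(1 - alpha / 2)
    return {
        "lag": lags,
        "percent": 100.0 * np.expm1(log_rr),
        "lo": 100.0 * np.expm1(log_rr - z * se),
        "hi": 100.0 * np.expm1(log_rr + z * se),
        "log_rr": log_rr,
    }
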