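"""Train/test utility evaluation of air quality indices.

The protocol mirrors operational use: the index parameters (single- and
multi-pollutant risk estimates) are estimated on the early part of each
city's series, the candidate indices are computed on the held-out later
part, and each index's *utility* is the pooled percent change in mortality
per interquartile-range (IQR) increase of the index on the test data,
estimated city by city with the same confounder adjustment as the main
models and pooled by random-effects meta-analysis. A spline version of the
test-stage regression gives the non-linear index-response curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .basis import moving_average, natural_cubic_basis
from .cgaim import bootstrap_weight_uncertainty, fit_cgaim
from .data import POLLUTANT_COLUMNS, CityDailySeries
from .dlnm import ModelConfig, confounder_design, linear_beta_city
from .errors import DegenerateBasisError, InvalidParameterError
from .glm import fit_quasipoisson
from .indices import (
    WHO_2021_SHORT_TERM,
    MultiPollutantParams,
    SinglePollutantParams,
    aqhi_value,
    aqi_chn,
    aqi_eu,
    aqi_usa,
    drf_multi,
    drf_single,
    make_aqhi_scale,
)
from .meta import pool_weights, re_meta_multivariate, re_meta_univariate

__all__ = [
    "ValidationConfig",
    "UtilityResult",
    "temporal_split",
    "utility_per_iqr",
    "index_response_curve",
    "compare_indices",
    "train_index_parameters",
    "compute_index_series",
]

logger = logging.getLogger(__name__)

INDEX_NAMES = ("aqi_usa", "aqi_eu", "aqi_chn", "aqhi_single", "aqhi_multi")


@dataclass(frozen=True)
class ValidationConfig:
    train_fraction: float = 0.7
    model: ModelConfig = dc_field(default_factory=ModelConfig)
    n_boot: int = 50
    block_length: int = 30
    seed: int = 0
    min_test_days: int = 365
    epa_dialect: str = "pre2024"
    who_guidelines: tuple[tuple[str, float], ...] = tuple(WHO_2021_SHORT_TERM.items())
    drf_exposure: str = "ma3"          # "ma3" | "same_day"

    @property
    def who(self) -> dict[str, float]:
        return dict(self.who_guidelines)


@dataclass
class UtilityResult:
    index_name: str
    scope: str
    percent_change: float
    ci_low: float
    ci_high: float
    iqr_used: float
    n_cities: int


def temporal_split(
    series: CityDailySeries, train_fraction: float = 0.7
) -> tuple[CityDailySeries, CityDailySeries]:
    """Split one city's series into contiguous early/late parts.

    The training part is the early ``train_fraction`` of days and strictly
    precedes the test part.
    """
    if not 0 < train_fraction < 1:
        raise InvalidParameterError("train_fraction must be in (0, 1)")
    n = len(series)
    n_train = int(n * train_fraction)
    if n_train < 1 or n_train >= n:
        raise InvalidParameterError("split leaves an empty part")
    return series.slice(0, n_train), series.slice(n_train, n)


def _exposure_matrix(series: CityDailySeries, config: ValidationConfig) -> np.ndarray:
    if config.drf_exposure == "ma3":
        return np.column_stack(
            [moving_average(series.pollutant(k), config.model.exposure_ma_window)
             for k in POLLUTANT_COLUMNS]
        )
    return series.pollutant_matrix()


def _city_index_fit(series, index_values, config: ModelConfig, basis=None):
    """Quasi-Poisson fit of deaths on the index (or its spline basis)."""
    z = np.asarray(index_values, dtype=float)
    conf, mask = confounder_design(series, config)
    mask = mask & np.isfinite(z) & np.isfinite(series.deaths)
    if basis is None:
        if np.ptp(z[mask]) == 0:
            raise DegenerateBasisError("index is constant on the test segment")
        block = z[mask, None]
    else:
        block = basis(z[mask])
    design = np.column_stack([block, conf[mask]])
    fit = fit_quasipoisson(series.deaths[mask], design)
    k = block.shape[1]
    return fit.coefficients[:k], fit.covariance[:k, :k]


def utility_per_iqr(
    test_series: list[CityDailySeries],
    index_values: dict[str, np.ndarray],
    iqr_scope: str = "overall",
    config: ValidationConfig | None = None,
    index_name: str = "index",
) -> UtilityResult:
    """Pooled percent change in mortality per IQR increase of the index.

    ``index_values`` maps city_id to the daily index on that city's test
    segment. The IQR is computed from the test-set index values, either
    pooled over all cities ('overall') or per country ('country' — the
    caller passes one country's cities). Cities with short test segments
    or a constant index are excluded with a logged warning.
    """
    config = config or ValidationConfig()
    if iqr_scope not in ("overall", "country"):
        raise InvalidParameterError(f"unknown iqr_scope {iqr_scope!r}")
    pooled_vals = np.concatenate(
        [np.asarray(index_values[s.city_id], float) for s in test_series]
    )
    pooled_vals = pooled_vals[np.isfinite(pooled_vals)]
    iqr = float(np.percentile(pooled_vals, 75) - np.percentile(pooled_vals, 25))
    if iqr <= 0:
        raise DegenerateBasisError("index IQR is zero on the test set")

    betas, variances = [], []
    for s in test_series:
        if len(s) < config.min_test_days:
            logger.warning("city %s excluded: test segment < %d days",
                           s.city_id, config.min_test_days)
            continue
        try:
            coef, cov = _city_index_fit(s, index_values[s.city_id], config.model)
        except Exception as exc:  # degenerate index / sparse data in one city
            logger.warning("city %s excluded from utility pooling: %s", s.city_id, exc)
            continue
        betas.append(float(coef[0]))
        variances.append(float(cov[0, 0]))
    if not betas:
        raise DegenerateBasisError("no city contributed a utility estimate")
    if len(betas) == 1:
        logger.info("single-city pooling: pass-through estimate")
        b, v = betas[0], variances[0]
    else:
        res = re_meta_univariate(np.array(betas), np.array(variances))
        b, v = res.scalar()
    z = stats.norm.ppf(0.975)
    se = np.sqrt(v)
    return UtilityResult(
        index_name=index_name,
        scope=iqr_scope,
        percent_change=100.0 * float(np.expm1(b * iqr)),
        ci_low=100.0 * float(np.expm1((b - z * se) * iqr)),
        ci_high=100.0 * float(np.expm1((b + z * se) * iqr)),
        iqr_used=iqr,
        n_cities=len(betas),
    )


def index_response_curve(
    test_series: list[CityDailySeries],
    index_values: dict[str, np.ndarray],
    config: ValidationConfig | None = None,
    n_grid: int = 50,
    reference: float | None = None,
) -> dict[str, np.ndarray]:
    """Pooled non-linear index-response curve on the test data.

    Each city's regression replaces the linear index term with a natural
    cubic spline whose two internal knots sit at the 25th/75th index
    percentiles averaged across cities (boundaries likewise averaged);
    city coefficient vectors are pooled by multivariate random-effects
    meta-analysis. The curve is the percent change relative to
    ``reference`` (default: the low end of the common range).
    """
    config = config or ValidationConfig()
    q25, q75, los, his = [], [], [], []
    for s in test_series:
        v = np.asarray(index_values[s.city_id], float)
        v = v[np.isfinite(v)]
        q25.append(np.percentile(v, 25))
        q75.append(np.percentile(v, 75))
        los.append(v.min())
        his.append(v.max())
    internal = np.unique([float(np.mean(q25)), float(np.mean(q75))])
    lo, hi = float(np.mean(los)), float(np.mean(his))
    internal = internal[(internal > lo) & (internal < hi)]

    def basis(z):
        return natural_cubic_basis(z, internal, (lo, hi))

    coefs, covs = [], []
    for s in test_series:
        try:
            coef, cov = _city_index_fit(s, index_values[s.city_id], config.model, basis)
        except Exception as exc:
            logger.warning("city %s excluded from curve pooling: %s", s.city_id, exc)
            continue
        coefs.append(coef)
        covs.append(cov)
    if not coefs:
        raise DegenerateBasisError("no city contributed a curve estimate")
    if len(coefs) == 1:
        pooled, pooled_cov = coefs[0], covs[0]
    else:
        res = re_meta_multivariate(np.array(coefs), covs)
        pooled, pooled_cov = res.pooled, res.pooled_cov

    grid = np.linspace(lo, hi, n_grid)
    ref = lo if reference is None else float(reference)
    contrast = basis(grid) - basis(np.full(n_grid, ref))
    log_rr = contrast @ pooled
    se = np.sqrt(np.clip(
        np.einsum("ij,jk,ik->i", contrast, pooled_cov, contrast), 0, None))
    z = stats.norm.ppf(0.975)
    return {
        "grid": grid,
        "percent": 100.0 * np.expm1(log_rr),
        "lo": 100.0 * np.expm1(log_rr - z * se),
        "hi": 100.0 * np.expm1(log_rr + z * se),
        "reference": ref,
    }


def train_index_parameters(
    train_series: list[CityDailySeries],
    config: ValidationConfig,
    country_id: str = "overall",
) -> tuple[list[SinglePollutantParams], MultiPollutantParams]:
    """Stage one + two on the training data: pooled betas, weights, slope."""
    single = []
    for k in POLLUTANT_COLUMNS:
        est, var = [], []
        for s in train_series:
            b, v = linear_beta_city(s, k, config.model)
            est.append(b)
            var.append(v)
        if len(est) == 1:
            logger.info("single-city country %s: pass-through pooling", country_id)
            b, v = est[0], var[0]
        else:
            b, v = re_meta_univariate(np.array(est), np.array(var)).scalar()
        single.append(SinglePollutantParams(country_id, k, b, max(v, 1e-12)))

    weights_list, covs, slopes, slope_vars = [], [], [], []
    for i, s in enumerate(train_series):
        fit = fit_cgaim(s, config.model, require_convergence=False)
        cov = bootstrap_weight_uncertainty(
            s, config.model, n_boot=config.n_boot,
            block_length=config.block_length,
            seed=np.random.SeedSequence(entropy=config.seed, spawn_key=(9999, i)),
        )
        weights_list.append(fit.weights)
        covs.append(cov)
        slopes.append(fit.beta_index)
        slope_vars.append(fit.beta_index_var)
    w_pooled, _ = pool_weights(np.array(weights_list), covs)
    if len(slopes) == 1:
        beta_c = slopes[0]
    else:
        beta_c, _ = re_meta_univariate(np.array(slopes), np.array(slope_vars)).scalar()
    if beta_c < 0:
        logger.warning("pooled mixture slope is negative (%.3g)", beta_c)
    multi = MultiPollutantParams(country_id, beta_c, tuple(w_pooled))
    return single, multi


def compute_index_series(
    series: CityDailySeries,
    index_name: str,
    config: ValidationConfig,
    single_params: list[SinglePollutantParams] | None = None,
    multi_params: MultiPollutantParams | None = None,
) -> np.ndarray:
    """Daily values of one index on a (test) series; NaN where unresolved."""
    x = _exposure_matrix(series, config)
    n = len(series)
    out = np.full(n, np.nan)
    ok = np.all(np.isfinite(x), axis=1)
    if index_name == "aqhi_single":
        scale = make_aqhi_scale(single_params, config.who)
        drf = np.array([drf_single(row, single_params) for row in x[ok]])
        out[ok] = aqhi_value(np.clip(drf, 0, None), scale)
    elif index_name == "aqhi_multi":
        scale = make_aqhi_scale(multi_params, config.who)
        drf = np.array([drf_multi(row, multi_params) for row in x[ok]])
        out[ok] = aqhi_value(np.clip(drf, 0, None), scale)
    elif index_name == "aqi_usa":
        out[ok] = [aqi_usa(row, dialect=config.epa_dialect) for row in x[ok]]
    elif index_name == "aqi_eu":
        out[ok] = [aqi_eu(row) for row in x[ok]]
    elif index_name == "aqi_chn":
        out[ok] = [aqi_chn(row) for row in x[ok]]
    else:
        raise InvalidParameterError(f"unknown index {index_name!r}")
    return out


def compare_indices(
    panel: list[CityDailySeries],
    config: ValidationConfig | None = None,
    index_names: tuple[str, ...] = INDEX_NAMES,
) -> pd.DataFrame:
    """Full utility protocol: fit on train, index the test set, rank indices.

    Returns one row per index per scope (overall plus any multi-country
    scopes present in the panel) with the percent change per IQR and CI.
    """
    config = config or ValidationConfig()
    splits = [temporal_split(s, config.train_fraction) for s in panel]
    trains = [tr for tr, _ in splits]
    tests = [te for _, te in splits]
    for tr, te in splits:
        assert tr.dates.max() < te.dates.min(), "train/test overlap"

    single, multi = train_index_parameters(trains, config)
    rows = []
    for name in index_names:
        values = {
            te.city_id: compute_index_series(te, name, config, single, multi)
            for te in tests
        }
        try:
            res = utility_per_iqr(tests, values, "overall", config, index_name=name)
        except DegenerateBasisError as exc:
            logger.warning("index %s: %s", name, exc)
            res = UtilityResult(name, "overall", np.nan, np.nan, np.nan, np.nan, 0)
        rows.append(res)
    return pd.DataFrame([r.__dict__ for r in rows])
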