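"""Synthetic multi-city daily panels with known ground truth.

Emulates the structure of city-level mortality / air-pollution time
series: seasonal, cross-correlated, right-skewed pollutant concentrations
(lognormal marginals — the canonical distribution for daily ambient
concentrations — with a sinusoidal annual cycle on the log scale and
correlated AR(1) innovations), seasonal
temperature and humidity, and overdispersed daily death counts whose
log-rate combines a baseline, a slow trend, day-of-week effects, a
U-shaped temperature term and a known pollutant effect — either a linear
effect of the weighted lag 0-2 mean index (the mixture ground truth) or
per-pollutant lag-distributed effects. Overdispersion is produced by a
gamma-Poisson (negative-binomial) mixture calibrated to a target Pearson
dispersion. Non-intercept log-rate components are centred so the realised
mean count matches the configured baseline.

All randomness flows from one master seed; city streams are derived
deterministically from the city index, so any city can be regenerated
independently of the panel.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import moving_average
from .data import POLLUTANT_COLUMNS, CityDailySeries
from .errors import InvalidParameterError

__all__ = [
    "SimulationConfig",
    "generate_city",
    "generate_panel",
    "write_truth",
    "read_truth",
]

_DEFAULT_CORR = (
    (1.00, 0.20, 0.40, 0.30),
    (0.20, 1.00, 0.10, 0.00),
    (0.40, 0.10, 1.00, 0.30),
    (0.30, 0.00, 0.30, 1.00),
)


@dataclass
class SimulationConfig:
    """Ground-truth settings for a synthetic panel (pm25, o3, no2, so2 order)."""

    n_cities: int = 8
    years: float = 5.0
    seed: int = 0
    start_date: str = "2010-01-01"
    # exposure process: lognormal marginals, exp(log mean - s^2/2 + seasonal + s*AR1).
    # City mean levels are drawn log-uniformly from `city_mean_ranges`,
    # emulating the wide spread of pollution levels across a multi-country
    # city network (clean through heavily polluted); set it to None to pin
    # every city at `pollutant_means`.
    pollutant_means: tuple[float, ...] = (35.0, 80.0, 30.0, 10.0)   # ug/m3
    city_mean_ranges: tuple[tuple[float, float], ...] | None = (
        (15.0, 90.0), (60.0, 120.0), (10.0, 60.0), (3.0, 50.0))
    pollutant_log_sds: tuple[float, ...] = (0.55, 0.30, 0.45, 0.65)
    seasonal_log_amplitudes: tuple[float, ...] = (0.25, 0.35, 0.20, 0.30)
    seasonal_peak_doy: tuple[float, ...] = (15.0, 196.0, 15.0, 15.0)
    ar_coef: float = 0.6
    correlation: tuple = _DEFAULT_CORR
    # outcome process
    true_weights: tuple[float, ...] = (0.35, 0.35, 0.20, 0.10)
    true_beta_index: float = 0.0006
    effect_mode: str = "index"              # "index" | "per_pollutant" | "none"
    pollutant_betas: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    lag_profile: tuple[float, ...] = (0.5, 0.3, 0.2, 0.0, 0.0, 0.0, 0.0, 0.0)
    baseline_deaths: float = 60.0
    trend_log_slope_per_year: float = -0.005
    dow_log_effects: tuple[float, ...] = (0.0, 0.005, 0.005, 0.0, 0.0, -0.01, -0.02)
    temp_effect_coef: float = 0.0004        # on (T - 20 degC)^2
    dispersion_target: float = 1.3
    # heterogeneity and missingness
    between_city_sd: float = 5e-5           # sd of city index slopes
    weight_jitter_sd: float = 0.05          # logistic-normal sd on weights
    missing_rates: tuple[float, ...] = (0.040, 0.021, 0.019, 0.053)

    def __post_init__(self):
        if self.years < 1:
            raise InvalidParameterError("years must be >= 1")
        if self.baseline_deaths <= 0:
            raise InvalidParameterError("baseline_deaths must be positive")
        w = np.asarray(self.true_weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise InvalidParameterError("true_weights must lie on the simplex")
        corr = np.asarray(self.correlation, dtype=float)
        if np.any(np.linalg.eigvalsh(corr) < -1e-10):
            raise InvalidParameterError("correlation matrix must be PSD")
        if self.effect_mode not in ("index", "per_pollutant", "none"):
            raise InvalidParameterError(f"unknown effect_mode {self.effect_mode!r}")


def _city_rng(config: SimulationConfig, city_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(city_index,))
    return np.random.default_rng(ss)


def _city_truth(config: SimulationConfig, rng: np.random.Generator) -> dict:
    w = np.asarray(config.true_weights, dtype=float)
    if config.weight_jitter_sd > 0:
        jitter = np.where(w > 0, np.exp(rng.normal(0, config.weight_jitter_sd, w.size)), 0.0)
        w = w * jitter
        w = w / w.sum()
    beta = config.true_beta_index + rng.normal(0, config.between_city_sd)
    return {"weights": w, "beta_index": float(beta)}


def _seasonal(n: int, doy: np.ndarray, amp: float, peak_doy: float) -> np.ndarray:
    return amp * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)


def _ar1_mvn(rng, n: int, corr: np.ndarray, ar: float) -> np.ndarray:
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(corr)))
    innov = rng.standard_normal((n, len(corr))) @ chol.T
    out = np.empty_like(innov)
    out[0] = innov[0]
    scale = np.sqrt(1.0 - ar**2)
    for t in range(1, n):
        out[t] = ar * out[t - 1] + scale * innov[t]
    return out


def _centered(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


def _expanding_ma3(x: np.ndarray) -> np.ndarray:
    """Lag 0-2 mean, using the available days at the series start."""
    ma = moving_average(x, 3)
    ma[0] = x[0]
    ma[1] = 0.5 * (x[0] + x[1])
    return ma


def generate_city(config: SimulationConfig, city_index: int) -> CityDailySeries:
    """Generate one city's daily series; ground truth rides in ``.truth``."""
    rng = _city_rng(config, city_index)
    n = int(round(config.years * 365.25))
    dates = pd.date_range(config.start_date, periods=n, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)

    # exposures
    corr = np.asarray(config.correlation, dtype=float)
    noise = _ar1_mvn(rng, n, corr, config.ar_coef)
    if config.city_mean_ranges is not None:
        means = np.exp([
            rng.uniform(np.log(lo), np.log(hi))
            for lo, hi in config.city_mean_ranges
        ])
    else:
        means = np.asarray(config.pollutant_means, dtype=float)
    pollutants = {}
    for j, name in enumerate(POLLUTANT_COLUMNS):
        s = config.pollutant_log_sds[j]
        log_series = (
            np.log(means[j])
            - 0.5 * s**2
            + _seasonal(n, doy, config.seasonal_log_amplitudes[j],
                        config.seasonal_peak_doy[j])
            + s * noise[:, j]
        )
        pollutants[name] = np.exp(log_series)

    temp = (
        15.0
        + 10.0 * np.cos(2 * np.pi * (doy - 196.0) / 365.25)
        + 3.0 * _ar1_mvn(rng, n, np.eye(1), 0.7)[:, 0]
    )
    rh = np.clip(
        70.0
        + 10.0 * np.cos(2 * np.pi * (doy - 15.0) / 365.25)
        + 8.0 * _ar1_mvn(rng, n, np.eye(1), 0.5)[:, 0],
        2.0,
        100.0,
    )

    truth = _city_truth(config, rng)
    x = np.column_stack([pollutants[k] for k in POLLUTANT_COLUMNS])
    if config.effect_mode == "index":
        ma = np.column_stack([_expanding_ma3(x[:, j]) for j in range(4)])
        effect = truth["beta_index"] * (ma @ truth["weights"])
    elif config.effect_mode == "per_pollutant":
        profile = np.asarray(config.lag_profile, dtype=float)
        betas = np.asarray(config.pollutant_betas, dtype=float)
        effect = np.zeros(n)
        for j in range(4):
            if betas[j] == 0:
                continue
            lagged = np.zeros(n)
            for lag, pl in enumerate(profile):
                if pl == 0:
                    continue
                shifted = np.empty(n)
                shifted[lag:] = x[: n - lag, j] if lag else x[:, j]
                shifted[:lag] = x[0, j]
                lagged += pl * shifted
            effect += betas[j] * lagged
    else:
        effect = np.zeros(n)

    t_years = np.arange(n) / 365.25
    dow = dates.dayofweek.to_numpy()
    log_rate = (
        np.log(config.baseline_deaths)
        + _centered(config.trend_log_slope_per_year * t_years)
        + _centered(np.asarray(config.dow_log_effects)[dow])
        + _centered(config.temp_effect_coef * (temp - 20.0) ** 2)
        + _centered(effect)
    )
    mu = np.exp(log_rate)
    if config.dispersion_target > 1.0:
        shape = config.baseline_deaths / (config.dispersion_target - 1.0)
        mu = mu * rng.gamma(shape, 1.0 / shape, size=n)
    deaths = rng.poisson(mu).astype(float)

    # MCAR missingness per pollutant
    for j, name in enumerate(POLLUTANT_COLUMNS):
        rate = config.missing_rates[j]
        if rate > 0:
            drop = rng.random(n) < rate
            pollutants[name] = np.where(drop, np.nan, pollutants[name])

    truth_rec = {
        "weights": [float(v) for v in truth["weights"]],
        "beta_index": truth["beta_index"],
        "effect_mode": config.effect_mode,
        "pollutant_means": [float(v) for v in means],
    }
    return CityDailySeries(
        city_id=f"city{city_index:03d}",
        country_id="SYN",
        dates=dates,
        deaths=deaths,
        pm25=pollutants["pm25"],
        o3=pollutants["o3"],
        no2=pollutants["no2"],
        so2=pollutants["so2"],
        temperature=temp,
        humidity=rh,
        truth=truth_rec,
    )


def generate_panel(config: SimulationConfig) -> tuple[list[CityDailySeries], dict]:
    """Generate all cities plus a serialisable truth record."""
    cities = [generate_city(config, i) for i in range(config.n_cities)]
    truth = {
        "config": asdict(config),
        "cities": {c.city_id: c.truth for c in cities},
    }
    # canonicalise to JSON-native types so the record round-trips losslessly
    return cities, json.loads(json.dumps(truth))


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
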