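"""Death risk functions, AQHI scaling, comparator AQIs and summaries.

The single-pollutant death risk function sums exponential excess risks,

    DRF-Single(x) = 100 * sum_k (exp(beta_k x_k) - 1)   [percent],

while the multi-pollutant version applies the mixture slope to the
weighted concentration sum,

    DRF-Multi(x) = beta_c * sum_k W_k x_k,

with W on the simplex. Either DRF is rescaled to the 1..10+ AQHI so that
the index equals 3 exactly where the WHO 2021 short-term guideline
concentrations are met:

    AQHI(x) = max(1, round_half_up(3 * DRF(x) / DRF(x_WHO))).

Comparator AQIs are the usual threshold constructions: per-pollutant
piecewise-linear sub-indices on published breakpoint tables (EPA for
AQI-USA, HJ 633-2012 IAQI for AQI-CHN) or band lookups (EEA for AQI-EU),
with the overall index the worst sub-index. Breakpoint tables ship as
versioned CSV resources; gas tables stated in ppm/ppb are applied after
converting the ug/m3 inputs at 25 degC and 1 atm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources as importlib_resources
from pathlib import Path

import numpy as np
import pandas as pd

from .data import POLLUTANT_COLUMNS
from .errors import InvalidParameterError

__all__ = [
    "SinglePollutantParams",
    "MultiPollutantParams",
    "AQHIScale",
    "IndexSeries",
    "WHO_2021_SHORT_TERM",
    "drf_single",
    "drf_multi",
    "make_aqhi_scale",
    "compute_aqhi",
    "categorize_aqhi",
    "aqi_usa",
    "aqi_eu",
    "aqi_chn",
    "contribution_shares",
    "monthly_category_counts",
]

#: WHO 2021 short-term air quality guideline levels (ug/m3):
#: PM2.5 24-h mean, O3 daily max 8-h mean, NO2 24-h mean, SO2 24-h mean.
WHO_2021_SHORT_TERM: dict[str, float] = {"pm25": 15.0, "o3": 100.0, "no2": 25.0, "so2": 40.0}

#: ug/m3 per ppb at 25 degC / 1 atm (molar volume 24.45 L/mol).
_UGM3_PER_PPB = {"o3": 48.00 / 24.45, "no2": 46.01 / 24.45, "so2": 64.07 / 24.45}

CATEGORIES = ("low", "moderate", "high", "very high")


@dataclass(frozen=True)
class SinglePollutantParams:
    """Per-country scalar log-RR per ug/m3 of one pollutant (3-day mean)."""

    country_id: str
    pollutant_id: str
    beta: float
    beta_var: float

    def __post_init__(self):
        if not np.isfinite(self.beta):
            raise InvalidParameterError("beta must be finite")
        if self.beta_var <= 0:
            raise InvalidParameterError("beta_var must be positive")


@dataclass(frozen=True)
class MultiPollutantParams:
    """Per-country mixture slope and simplex pollutant weights."""

    country_id: str
    beta_c: float
    weights: tuple[float, ...]          # ordered pm25, o3, no2, so2
    pollutants: tuple[str, ...] = POLLUTANT_COLUMNS

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < -1e-10) or abs(w.sum() - 1.0) > 1e-8:
            raise InvalidParameterError("weights must lie on the simplex")
        if not np.isfinite(self.beta_c):
            raise InvalidParameterError("beta_c must be finite")


def _as_vector(x, pollutants=POLLUTANT_COLUMNS) -> np.ndarray:
    if isinstance(x, dict):
        v = np.array([x[k] for k in pollutants], dtype=float)
    else:
        v = np.asarray(x, dtype=float)
    if np.any(v < 0):
        raise InvalidParameterError("concentrations must be nonnegative")
    return v


def drf_single(x, betas) -> float:
    """Percent excess mortality risk, summed over pollutants.

    ``betas`` is a sequence of :class:`SinglePollutantParams` (or plain
    floats) ordered like ``x`` (pm25, o3, no2, so2).
    """
    xv = _as_vector(x)
    bv = np.array(
        [b.beta if isinstance(b, SinglePollutantParams) else float(b) for b in betas]
    )
    if bv.size != xv.size:
        raise InvalidParameterError("betas and concentrations must align")
    return float(100.0 * np.sum(np.expm1(bv * xv)))


def drf_multi(x, params: MultiPollutantParams) -> float:
    """Mixture death risk: beta_c times the weighted concentration sum."""
    xv = _as_vector(x, params.pollutants)
    w = np.asarray(params.weights, dtype=float)
    return float(params.beta_c * np.sum(w * xv))


@dataclass(frozen=True)
class AQHIScale:
    """Anchor for rescaling a DRF to the 1..10+ AQHI."""

    drf_at_who: float
    who_guidelines: dict = field(default_factory=lambda: dict(WHO_2021_SHORT_TERM))
    anchor_value: int = 3

    def __post_init__(self):
        if not self.drf_at_who > 0:
            raise InvalidParameterError("DRF at the WHO guidelines must be positive")


def make_aqhi_scale(params, who_guidelines: dict | None = None) -> AQHIScale:
    """Anchor the index: AQHI = 3 where the WHO guidelines are met.

    ``params`` is either :class:`MultiPollutantParams` or a sequence of
    :class:`SinglePollutantParams` (one per pollutant).
    """
    who = dict(who_guidelines or WHO_2021_SHORT_TERM)
    if isinstance(params, MultiPollutantParams):
        anchor = drf_multi(who, params)
    else:
        order = [b.pollutant_id for b in params]
        anchor = drf_single([who[k] for k in order], params)
    return AQHIScale(drf_at_who=anchor, who_guidelines=who)


def _round_half_up(v: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(v, dtype=float) + 0.5)


def aqhi_value(drf, scale: AQHIScale):
    """Scale DRF values to integers: 3 at the anchor, floored at 1."""
    drf = np.asarray(drf, dtype=float)
    raw = scale.anchor_value * drf / scale.drf_at_who
    return np.maximum(1, _round_half_up(raw)).astype(int)


def categorize_aqhi(value: int) -> str:
    """Risk category: low (1-3), moderate (4-6), high (7-10), very high (>10)."""
    v = int(value)
    if v < 1:
        raise InvalidParameterError("AQHI values start at 1")
    if v <= 3:
        return "low"
    if v <= 6:
        return "moderate"
    if v <= 10:
        return "high"
    return "very high"


@dataclass
class IndexSeries:
    """Daily index values with risk-category labels."""

    dates: pd.DatetimeIndex
    values: np.ndarray
    categories: list[str] | None = None
    name: str = "aqhi"


def compute_aqhi(drf_series, scale: AQHIScale, dates=None, name="aqhi") -> IndexSeries:
    """Daily integer AQHI (1..10+) with category labels from DRF values."""
    vals = aqhi_value(drf_series, scale)
    cats = [categorize_aqhi(v) for v in vals]
    if dates is None:
        dates = pd.date_range("2000-01-01", periods=len(vals), freq="D")
    return IndexSeries(dates=pd.DatetimeIndex(dates), values=vals, categories=cats, name=name)


# ---------------------------------------------------------------------------
# Comparator AQIs


def _resource_path(name: str) -> Path:
    return Path(importlib_resources.files("aqhimix.resources") / name)


@lru_cache(maxsize=8)
def _load_table(name: str) -> pd.DataFrame:
    return pd.read_csv(_resource_path(name))


def _truncate(value: float, decimals: int) -> float:
    scale = 10.0**decimals
    return math.floor(value * scale + 1e-9) / scale


def _to_table_units(conc_ugm3: float, pollutant: str, units: str) -> float:
    if units == "ug/m3":
        return conc_ugm3
    ppb = conc_ugm3 / _UGM3_PER_PPB[pollutant]
    return ppb / 1000.0 if units == "ppm" else ppb


def usa_table_top(pollutant: str, dialect: str = "pre2024") -> float:
    """Upper concentration bound (ug/m3) of the pollutant's highest interval."""
    tab = _load_table(f"aqi_usa_{dialect}.csv")
    rows = tab[tab.pollutant == pollutant]
    top = rows.iloc[-1]
    conc = float(top.conc_high)
    if top.units == "ppm":
        conc *= 1000.0
    if top.units != "ug/m3":
        conc *= _UGM3_PER_PPB[pollutant]
    return conc


def _usa_subindex(conc_ugm3: float, pollutant: str, tab: pd.DataFrame) -> float:
    rows = tab[tab.pollutant == pollutant].reset_index(drop=True)
    c = _to_table_units(conc_ugm3, pollutant, rows.units.iloc[0])
    c = _truncate(c, int(rows.truncate_decimals.iloc[0]))
    for _, r in rows.iterrows():
        if c <= r.conc_high:
            lo, hi = r.conc_low, r.conc_high
            frac = 0.0 if hi == lo else (c - lo) / (hi - lo)
            return r.aqi_low + frac * (r.aqi_high - r.aqi_low)
    # beyond the table: extend with the last segment's slope ("500+")
    r = rows.iloc[-1]
    slope = (r.aqi_high - r.aqi_low) / (r.conc_high - r.conc_low)
    return r.aqi_high + slope * (c - r.conc_high)


def aqi_usa(x, dialect: str = "pre2024") -> int:
    """EPA AQI (0..500+): max over per-pollutant piecewise-linear sub-indices.

    ``x`` maps pollutant ids to ug/m3 concentrations (PM2.5 24-h, O3 8-h
    max, NO2 and SO2 daily values applied to the table's metric).
    """
    xv = _as_vector(x)
    tab = _load_table(f"aqi_usa_{dialect}.csv")
    subs = [
        _usa_subindex(c, k, tab) for k, c in zip(POLLUTANT_COLUMNS, xv)
    ]
    return int(round(max(subs)))


def aqi_eu(x, edition: str = "2023") -> int:
    """EEA European AQ index band 1..6: worst per-pollutant band."""
    xv = _as_vector(x)
    tab = _load_table(f"aqi_eu_{edition}.csv")
    worst = 1
    for k, c in zip(POLLUTANT_COLUMNS, xv):
        rows = tab[tab.pollutant == k]
        band = 6
        for _, r in rows.iterrows():
            if c <= r.conc_high:
                band = int(r.band)
                break
        worst = max(worst, band)
    return worst


def aqi_chn(x) -> int:
    """Chinese AQI (HJ 633-2012 IAQI): max sub-index, ceiling-rounded.

    Piecewise-linear between the standard's concentration/IAQI nodes for
    24-h PM2.5, NO2 and SO2 and 8-h O3; beyond the top node the last
    segment is extended ("300+"/"500+").
    """
    xv = _as_vector(x)
    tab = _load_table("aqi_chn_hj633_2012.csv")
    subs = []
    for k, c in zip(POLLUTANT_COLUMNS, xv):
        rows = tab[tab.pollutant == k]
        conc = rows.conc.to_numpy(dtype=float)
        iaqi = rows.iaqi.to_numpy(dtype=float)
        if c <= conc[-1]:
            subs.append(float(np.interp(c, conc, iaqi)))
        else:
            slope = (iaqi[-1] - iaqi[-2]) / (conc[-1] - conc[-2])
            subs.append(iaqi[-1] + slope * (c - conc[-1]))
    return int(math.ceil(max(subs) - 1e-9))


# ---------------------------------------------------------------------------
# Contribution shares and category-day summaries


def contribution_shares(
    params: MultiPollutantParams, x_series=None, mode: str = "weights"
) -> np.ndarray:
    """Per-pollutant percent contributions to the mixture index.

    mode 'weights' returns 100*W_k; mode 'concentration_weighted'
    returns 100*W_k*xbar_k / sum_j W_j*xbar_j over the supplied period
    (used for seasonal/temporal shares).
    """
    w = np.asarray(params.weights, dtype=float)
    if mode == "weights":
        return 100.0 * w / w.sum()
    if mode != "concentration_weighted":
        raise InvalidParameterError(f"unknown mode {mode!r}")
    if x_series is None:
        raise InvalidParameterError("concentration_weighted mode needs x_series")
    xbar = np.nanmean(np.asarray(x_series, dtype=float).reshape(-1, w.size), axis=0)
    num = w * xbar
    if num.sum() <= 0:
        raise InvalidParameterError("degenerate concentration-weighted shares")
    return 100.0 * num / num.sum()


def monthly_category_counts(index_series: IndexSeries) -> tuple[pd.DataFrame, dict[str, float]]:
    """Calendar-month day counts per risk category plus OLS trend slopes.

    Returns (counts, slopes): ``counts`` has one row per calendar month
    and one column per category; ``slopes`` maps each category to the
    least-squares slope of its count against the month index (days per
    month per month).
    """
    df = pd.DataFrame(
        {
            "month": index_series.dates.to_period("M"),
            "category": index_series.categories
            or [categorize_aqhi(v) for v in index_series.values],
        }
    )
    counts = (
        df.groupby(["month", "category"], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
    )
    t = np.arange(len(counts), dtype=float)
    slopes = {}
    for cat in CATEGORIES:
        yv = counts[cat].to_numpy(dtype=float)
        slopes[cat] = float(np.polyfit(t, yv, 1)[0]) if len(t) > 1 else 0.0
    return counts, slopes
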