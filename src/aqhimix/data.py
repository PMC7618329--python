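"""City-level daily time series container and CSV round-trip.

The on-disk schema is a plain CSV with columns
``date, deaths, pm25, o3, no2, so2, temp, rh`` (ISO-8601 dates, one row
per calendar day, gap-free). Pollutants are daily means in ug/m3 except
``o3`` which is the daily maximum 8-h mean; ``temp`` is degrees C and
``rh`` percent relative humidity. Missing pollutant values are empty cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["CityDailySeries", "POLLUTANT_COLUMNS", "read_city_csv", "write_city_csv"]

POLLUTANT_COLUMNS = ("pm25", "o3", "no2", "so2")
REQUIRED_COLUMNS = ("date", "deaths") + POLLUTANT_COLUMNS + ("temp", "rh")


@dataclass
class CityDailySeries:
    """Aligned daily mortality / exposure / covariate records for one city."""

    city_id: str
    country_id: str
    dates: pd.DatetimeIndex
    deaths: np.ndarray
    pm25: np.ndarray
    o3: np.ndarray
    no2: np.ndarray
    so2: np.ndarray
    temperature: np.ndarray
    humidity: np.ndarray
    truth: dict = field(default_factory=dict)  # simulation ground truth, if any

    def __post_init__(self) -> None:
        n = len(self.dates)
        arrays = {
            "deaths": self.deaths, "pm25": self.pm25, "o3": self.o3,
            "no2": self.no2, "so2": self.so2,
            "temperature": self.temperature, "humidity": self.humidity,
        }
        for name, arr in arrays.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n,):
                raise SchemaError(f"{name} length {arr.shape} != {n} dates")
            setattr(self, name, arr)
        diffs = np.diff(self.dates.values).astype("timedelta64[D]")
        if len(self.dates) > 1 and not np.all(diffs == np.timedelta64(1, "D")):
            raise SchemaError("dates must be consecutive calendar days")
        if np.nanmin(self.deaths) < 0:
            raise SchemaError("deaths must be nonnegative")
        for k in POLLUTANT_COLUMNS:
            v = self.pollutant(k)
            if np.any(v[np.isfinite(v)] < 0):
                raise SchemaError(f"{k} concentrations must be nonnegative")
        hum = self.humidity[np.isfinite(self.humidity)]
        if hum.size and (hum.min() < 0 or hum.max() > 100):
            raise SchemaError("humidity must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def n_years(self) -> float:
        return len(self.dates) / 365.25

    def pollutant(self, pollutant_id: str) -> np.ndarray:
        if pollutant_id not in POLLUTANT_COLUMNS:
            raise KeyError(f"unknown pollutant {pollutant_id!r}")
        return getattr(self, pollutant_id)

    def pollutant_matrix(self) -> np.ndarray:
        """(n_days, 4) matrix ordered pm25, o3, no2, so2."""
        return np.column_stack([self.pollutant(k) for k in POLLUTANT_COLUMNS])

    def slice(self, start: int, stop: int) -> "CityDailySeries":
        return CityDailySeries(
            city_id=self.city_id,
            country_id=self.country_id,
            dates=self.dates[start:stop],
            deaths=self.deaths[start:stop],
            pm25=self.pm25[start:stop],
            o3=self.o3[start:stop],
            no2=self.no2[start:stop],
            so2=self.so2[start:stop],
            temperature=self.temperature[start:stop],
            humidity=self.humidity[start:stop],
            truth=self.truth,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates.strftime("%Y-%m-%d"),
                "deaths": self.deaths.astype(int),
                "pm25": self.pm25,
                "o3": self.o3,
                "no2": self.no2,
                "so2": self.so2,
                "temp": self.temperature,
                "rh": self.humidity,
            }
        )


def read_city_csv(path: str | Path, city_id: str | None = None,
                  country_id: str = "") -> CityDailySeries:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    dates = pd.DatetimeIndex(pd.to_datetime(df["date"], format="ISO8601"))
    return CityDailySeries(
        city_id=city_id or path.stem,
        country_id=country_id,
        dates=dates,
        deaths=df["deaths"].to_numpy(dtype=float),
        pm25=df["pm25"].to_numpy(dtype=float),
        o3=df["o3"].to_numpy(dtype=float),
        no2=df["no2"].to_numpy(dtype=float),
        so2=df["so2"].to_numpy(dtype=float),
        temperature=df["temp"].to_numpy(dtype=float),
        humidity=df["rh"].to_numpy(dtype=float),
    )


def write_city_csv(series: CityDailySeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False, float_format="%.4f")
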