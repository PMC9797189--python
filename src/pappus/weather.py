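"""Hourly meteorological records: filtering, relative humidity, wet/dry split.

Dispersal is driven by the joint behaviour of wind speed and humidity:
pappi close when air is moist, and wet hours tend to be calm.  This module
ingests hourly surface observations (timestamp, 10 m wind speed,
temperature, dewpoint), derives relative humidity with the Magnus formula,
restricts to the dandelion reproductive season (April-October, on-the-hour,
complete records), and splits wind speeds into dry (RH < 90%) and wet
(RH >= 90%) classes for downstream sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MAGNUS_A",
    "MAGNUS_B",
    "WET_RH_THRESHOLD",
    "WeatherDataset",
    "compute_rh",
    "filter_records",
    "classify",
    "split",
    "sample_wind",
    "summarize_weather",
]

MAGNUS_A = 17.625
MAGNUS_B = 243.04  # deg C
WET_RH_THRESHOLD = 90.0  # % RH at/above which plant surfaces are taken as wet
SEASON_MONTHS = range(4, 11)  # April .. October inclusive
DEWPOINT_TOLERANCE = 0.5  # deg C of supersaturation tolerated before rejection


def compute_rh(temperature, dewpoint):
    """Relative humidity (%) from dry-bulb and dewpoint temperature (deg C).

    Uses the Magnus approximation for saturation vapour pressure,
    ``e_s(T) = C exp(a T / (b + T))`` with a = 17.625, b = 243.04 deg C, so

        RH = 100 * exp(a Td/(b + Td) - a T/(b + T)).

    Dewpoints up to 0.5 deg C above the dry-bulb temperature (sensor
    rounding) are clamped to saturation; larger excesses raise.
    """
    t = np.asarray(temperature, dtype=float)
    td = np.asarray(dewpoint, dtype=float)
    if np.any(td > t + DEWPOINT_TOLERANCE):
        raise ValueError("dewpoint exceeds temperature beyond tolerance")
    rh = 100.0 * np.exp(MAGNUS_A * td / (MAGNUS_B + td) - MAGNUS_A * t / (MAGNUS_B + t))
    rh = np.minimum(rh, 100.0)
    if rh.ndim == 0:
        return float(rh)
    return rh


def classify(rh):
    """Classify hour(s) as ``"wet"`` (RH >= 90%) or ``"dry"`` (RH < 90%)."""
    wet = np.asarray(rh, dtype=float) >= WET_RH_THRESHOLD
    out = np.where(wet, "wet", "dry")
    if out.ndim == 0:
        return str(out)
    return out


@dataclass
class WeatherDataset:
    """Filtered hourly records with derived RH and wet/dry class."""

    records: pd.DataFrame
    provenance: str = ""
    dropped: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def wind_speed(self) -> np.ndarray:
        return self.records["wind_speed"].to_numpy()

    @property
    def rh(self) -> np.ndarray:
        return self.records["rh"].to_numpy()


def filter_records(raw: pd.DataFrame, provenance: str = "") -> WeatherDataset:
    """Filter raw hourly rows to the analysis dataset.

    Keeps rows that (i) have wind speed, temperature and dewpoint present,
    (ii) fall on the hour, (iii) fall in April-October, and (iv) have a
    physically consistent dewpoint.  Computes RH and the wet/dry class.
    Counts of rows dropped per rule are recorded on the result.

    Expected columns: ``timestamp`` (parseable to datetime), ``wind_speed``
    (m s^-1 at 10 m), ``temperature``, ``dewpoint`` (deg C).
    """
    df = raw.copy()
    dropped: dict[str, int] = {}
    df["timestamp"] = pd.to_datetime(df["timestamp"])

    complete = df[["wind_speed", "temperature", "dewpoint"]].notna().all(axis=1)
    dropped["missing"] = int((~complete).sum())
    df = df[complete]

    on_hour = (df["timestamp"].dt.minute == 0) & (df["timestamp"].dt.second == 0)
    dropped["off-hour"] = int((~on_hour).sum())
    df = df[on_hour]

    in_season = df["timestamp"].dt.month.isin(list(SEASON_MONTHS))
    dropped["out-of-season"] = int((~in_season).sum())
    df = df[in_season]

    consistent = df["dewpoint"] <= df["temperature"] + DEWPOINT_TOLERANCE
    nonneg = df["wind_speed"] >= 0
    dropped["inconsistent"] = int((~(consistent & nonneg)).sum())
    df = df[consistent & nonneg].reset_index(drop=True)

    if len(df) == 0:
        raise ValueError("no records survive filtering (empty dataset)")

    df["rh"] = compute_rh(df["temperature"].to_numpy(), df["dewpoint"].to_numpy())
    df["weather_class"] = classify(df["rh"].to_numpy())
    return WeatherDataset(records=df, provenance=provenance, dropped=dropped)


def split(dataset: WeatherDataset) -> tuple[np.ndarray, np.ndarray]:
    """Partition wind speeds into (dry, wet) arrays by the RH threshold."""
    cls = dataset.records["weather_class"].to_numpy()
    u = dataset.wind_speed
    return u[cls == "dry"], u[cls == "wet"]


def sample_wind(speeds: np.ndarray, n: int, seed) -> np.ndarray:
    """Bootstrap ``n`` wind speeds (i.i.d. with replacement) from a class.

    ``seed`` may be an int or a ``numpy.random.Generator``; equal seeds give
    identical draws.
    """
    speeds = np.asarray(speeds, dtype=float)
    if speeds.size == 0:
        raise ValueError("cannot sample from an empty wind-speed distribution")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.choice(speeds, size=int(n), replace=True)


def summarize_weather(dataset: WeatherDataset) -> dict:
    """Validation summary: counts, means, RH range, class frequencies."""
    dry, wet = split(dataset)
    return {
        "n_records": len(dataset),
        "dropped": dict(dataset.dropped),
        "mean_wind_m_s": float(np.mean(dataset.wind_speed)),
        "mean_rh_percent": float(np.mean(dataset.rh)),
        "rh_range_percent": [float(dataset.rh.min()), float(dataset.rh.max())],
        "frequency_dry": float(len(dry) / len(dataset)),
        "mean_wind_dry": float(dry.mean()) if dry.size else None,
        "mean_wind_wet": float(wet.mean()) if wet.size else None,
    }
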