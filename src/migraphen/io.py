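"""Plain-text table I/O for the pipeline's external formats."""
from __future__ import annotations

import numpy as np
import pandas as pd

ISO_FMT = "%Y-%m-%dT%H:%M:%SZ"


def write_tracks_csv(tracks: pd.DataFrame, path) -> None:
    out = tracks.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).tz_convert("UTC").strftime(ISO_FMT)
    out[["bird_id", "timestamp", "lon", "lat"]].to_csv(path, index=False)


def read_tracks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def write_ndvi_csv(ndvi: pd.DataFrame, path) -> None:
    out = ndvi.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out[["region", "date", "ndvi"]].to_csv(path, index=False)


def read_ndvi_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_weather_csv(weather: pd.DataFrame, path) -> None:
    out = weather.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out[["station_id", "date", "tmean_c", "prcp_cm"]].to_csv(path, index=False)


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    return df


def read_points_csv(path) -> np.ndarray:
    """Colony / survey-site points as ``name,lon,lat`` -> (n, 2) lon/lat."""
    df = pd.read_csv(path)
    return df[["lon", "lat"]].to_numpy(dtype=float)


def write_truth_csv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)
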