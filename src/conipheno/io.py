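"""Readers and writers for the pipeline's CSV/JSON file formats.

Conventions: ISO-8601 dates in local standard time, 1-based day of year,
AmeriFlux-style column names and the -9999 missing-value sentinel honored
on read (writes use empty cells).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_roi_csv",
    "write_roi_csv",
    "read_flux_csv",
    "write_flux_csv",
    "read_weather_csv",
    "write_weather_csv",
    "read_spectra_csv",
    "write_spectra_csv",
    "write_transitions_csv",
    "read_transitions_csv",
    "write_truth_json",
    "read_truth_json",
]

MISSING_SENTINEL = -9999


def _replace_sentinel(df: pd.DataFrame) -> pd.DataFrame:
    return df.replace(MISSING_SENTINEL, np.nan).replace(float(MISSING_SENTINEL), np.nan)


def read_roi_csv(path) -> pd.DataFrame:
    """ROI color CSV -> image records (timestamp, r_dn, g_dn, b_dn,
    solar_elevation, snow_flag). One row per image."""
    df = pd.read_csv(path)
    required = {"date", "local_std_time", "solar_elev", "r_mean", "g_mean", "b_mean", "snow_flag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ROI CSV missing columns: {sorted(missing)}")
    ts = pd.to_datetime(df["date"].astype(str) + " " + df["local_std_time"].astype(str))
    out = pd.DataFrame(
        {
            "timestamp": ts,
            "r_dn": df["r_mean"].astype(float),
            "g_dn": df["g_mean"].astype(float),
            "b_dn": df["b_mean"].astype(float),
            "solar_elevation": df["solar_elev"].astype(float),
            "snow_flag": df["snow_flag"].astype(bool),
        }
    )
    for c in ("r_dn", "g_dn", "b_dn"):
        bad = (out[c] < 0) | (out[c] > 255)
        if bad.any():
            raise ValueError(
                f"{c} out of [0,255] at rows {out.index[bad].tolist()[:10]}"
            )
    return out


def write_roi_csv(records: pd.DataFrame, path) -> None:
    ts = pd.to_datetime(records["timestamp"])
    out = pd.DataFrame(
        {
            "date": ts.dt.strftime("%Y-%m-%d"),
            "local_std_time": ts.dt.strftime("%H:%M:%S"),
            "solar_elev": records["solar_elevation"],
            "r_mean": records["r_dn"],
            "g_mean": records["g_dn"],
            "b_mean": records["b_dn"],
            "snow_flag": records["snow_flag"].astype(int),
        }
    )
    out.to_csv(path, index=False)


def read_flux_csv(path) -> pd.DataFrame:
    """AmeriFlux-like half-hourly CSV (TIMESTAMP_START, NEE, PPFD_IN, TA,
    USTAR; -9999 = missing) -> flux records."""
    df = pd.read_csv(path)
    required = {"TIMESTAMP_START", "NEE", "PPFD_IN", "TA", "USTAR"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"flux CSV missing columns: {sorted(missing)}")
    df = _replace_sentinel(df)
    ts = pd.to_datetime(df["TIMESTAMP_START"].astype("Int64").astype(str), format="%Y%m%d%H%M")
    out = pd.DataFrame(
        {
            "timestamp": ts,
            "nee": df["NEE"].astype(float),
            "ppfd": df["PPFD_IN"].astype(float),
            "tair": df["TA"].astype(float),
            "ustar": df["USTAR"].astype(float),
        }
    )
    out["gap_flag"] = out["nee"].isna()
    return out


def write_flux_csv(records: pd.DataFrame, path) -> None:
    ts = pd.to_datetime(records["timestamp"])
    out = pd.DataFrame(
        {
            "TIMESTAMP_START": ts.dt.strftime("%Y%m%d%H%M"),
            "NEE": records["nee"],
            "PPFD_IN": records["ppfd"],
            "TA": records["tair"],
            "USTAR": records["ustar"],
        }
    )
    out.to_csv(path, index=False)


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"date", "tmax", "tmin"} - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV missing columns: {sorted(missing)}")
    df = _replace_sentinel(df)
    df["date"] = pd.to_datetime(df["date"])
    bad = df["tmin"] > df["tmax"]
    if bad.any():
        raise ValueError(f"tmin > tmax at rows {df.index[bad].tolist()[:10]}")
    return df[["date", "tmax", "tmin"]]


def write_weather_csv(weather: pd.DataFrame, path) -> None:
    out = weather.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_spectra_csv(path) -> tuple[pd.DataFrame, np.ndarray]:
    """Spectra CSV (date, tree_id, one column per nm) -> (frame, grid)."""
    df = pd.read_csv(path)
    wl_cols = [c for c in df.columns if c not in ("date", "tree_id")]
    wl = np.array([float(c) for c in wl_cols])
    df["date"] = pd.to_datetime(df["date"])
    return df, wl


def write_spectra_csv(spectra: pd.DataFrame, path) -> None:
    out = spectra.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_transitions_csv(trans: pd.DataFrame, path, site: str = "", metric: str = "") -> None:
    out = trans.copy()
    if site:
        out.insert(0, "site", site)
    if metric:
        out.insert(1 if site else 0, "metric", metric)
    out.to_csv(path, index=False)


def read_transitions_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth_json(truth: dict, path) -> None:
    """Serialize a synthetic-site truth record (params, latent trajectory,
    true transition dates) for recovery tests."""
    from .model import ModelParams

    def convert(obj):
        if isinstance(obj, ModelParams):
            return {"__model_params__": obj.__dict__}
        if isinstance(obj, pd.DataFrame):
            d = obj.copy()
            for c in d.columns:
                if np.issubdtype(d[c].dtype, np.datetime64):
                    d[c] = d[c].dt.strftime("%Y-%m-%d")
            return {"__frame__": d.to_dict(orient="list")}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating, np.bool_)):
            return obj.item()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(truth, default=convert, indent=1))


def read_truth_json(path) -> dict:
    from .model import ModelParams

    def hook(d):
        if "__model_params__" in d:
            return ModelParams(**d["__model_params__"])
        if "__frame__" in d:
            return pd.DataFrame(d["__frame__"])
        return d

    return json.loads(Path(path).read_text(), object_hook=hook)
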