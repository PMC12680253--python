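"""CSV readers/writers for the three input schemas.

Weather: one file per environment with ISO dates and columns
``date,tmin,tmax,rainfall,irrigation,etp[,humidity,par,hours_above_30,deficit]``.
Trial tables: tidy long form ``year,site,condition,hybrid,block,row,col,trait,value``.
Segmentation: one row per cross-section, one column per zone plus ``total_px``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .traits import ZONES

__all__ = [
    "read_weather_csv",
    "write_weather_csv",
    "read_trial_csv",
    "write_trial_csv",
    "read_segmentation_csv",
]

_WEATHER_REQUIRED = ("date", "tmax", "rainfall", "irrigation", "etp")


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_WEATHER_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: weather CSV missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if not df["date"].is_monotonic_increasing or df["date"].duplicated().any():
        raise ValueError(f"{path}: dates must be strictly increasing")
    for col in ("rainfall", "irrigation", "etp"):
        if (df[col] < 0).any():
            raise ValueError(f"{path}: negative {col}")
    return df


def write_weather_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_trial_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"condition", "hybrid", "block", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: trial CSV missing columns {sorted(missing)}")
    return df


def write_trial_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_segmentation_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    zone_cols = [c for c in df.columns if c in ZONES]
    if not zone_cols:
        raise ValueError(f"{path}: no recognised zone columns")
    if "total_px" not in df.columns:
        df["total_px"] = df[zone_cols].sum(axis=1)
    return df
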