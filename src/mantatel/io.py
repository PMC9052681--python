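"""Readers, writers and time handling for the telemetry tables.

All tables are carried as pandas DataFrames with fixed column contracts:

* detections:  ``timestamp`` (UTC), ``receiver_id``, ``tag_id``
* receivers:   ``receiver_id``, ``lat``, ``lon``, ``region``,
  ``active_start``, ``active_end`` (one row per active interval)
* deployments: ``animal_id``, ``tag_id``, ``release_time``, ``sex``,
  ``wingspan_cm``, ``maturity``, ``satellite_tag``
* environment: ``date``, ``chla``, ``moon_frac``

Timestamps are stored tz-aware in UTC.  Calendar-day operations apply a fixed
configurable offset (default +03:00, local time at the study site) because a
"calendar day" is only defined once a day boundary is chosen.
"""

from __future__ import annotations

import logging
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("mantatel")

REGIONS = ("CH", "C", "W", "S", "N", "OFFSHORE")

#: order that makes detection processing deterministic for tied timestamps
DETECTION_SORT = ["tag_id", "timestamp", "receiver_id"]


def to_calendar_day(timestamps, tz_offset_hours: float = 3.0):
    """Map UTC timestamps to local calendar dates using a fixed offset.

    Works on a scalar Timestamp or a datetime Series; returns date(s).
    """
    off = pd.Timedelta(hours=tz_offset_hours)
    if isinstance(timestamps, pd.Series):
        return (timestamps + off).dt.date
    ts = pd.Timestamp(timestamps)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return (ts + off).date()


def _parse_utc(series: pd.Series, what: str, path) -> pd.Series:
    parsed = pd.to_datetime(series, utc=True, format="ISO8601", errors="coerce")
    bad = parsed.isna() & series.notna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # +2: header + 1-based
        raise ValueError(
            f"{path}: unparseable {what} on line(s) {lines[:10]}"
            + (" ..." if len(lines) > 10 else "")
        )
    return parsed


def read_receivers(path) -> pd.DataFrame:
    """Read the station table; one row per (receiver, active interval)."""
    df = pd.read_csv(path, dtype={"receiver_id": str, "region": str})
    required = {"receiver_id", "lat", "lon", "region", "active_start", "active_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["lat"].abs() > 90).any() or ((df["lon"] <= -180) | (df["lon"] > 180)).any():
        raise ValueError(f"{path}: receiver coordinates out of range")
    unknown = set(df["region"]) - set(REGIONS)
    if unknown:
        raise ValueError(f"{path}: unknown region code(s) {sorted(unknown)}")
    df["active_start"] = _parse_utc(df["active_start"], "active_start", path)
    df["active_end"] = _parse_utc(df["active_end"], "active_end", path)
    if (df["active_end"] < df["active_start"]).any():
        raise ValueError(f"{path}: active_end precedes active_start")
    # intervals of one receiver must not overlap
    for rid, grp in df.groupby("receiver_id"):
        g = grp.sort_values("active_start")
        if (g["active_start"].iloc[1:].to_numpy() < g["active_end"].iloc[:-1].to_numpy()).any():
            raise ValueError(f"{path}: overlapping active intervals for receiver {rid}")
    return df.sort_values(["receiver_id", "active_start"]).reset_index(drop=True)


def station_positions(receivers: pd.DataFrame) -> pd.DataFrame:
    """Collapse the interval table to one row per receiver (id, lat, lon, region)."""
    pos = receivers.drop_duplicates("receiver_id")[["receiver_id", "lat", "lon", "region"]]
    return pos.set_index("receiver_id")


def read_detections(path, receivers: pd.DataFrame) -> pd.DataFrame:
    """Read a raw detections CSV and validate it against the station table.

    Returns records sorted by (tag_id, timestamp, receiver_id).  Rows naming a
    receiver absent from the station table are a hard error listing the ids.
    """
    df = pd.read_csv(path, dtype={"receiver_id": str, "tag_id": str})
    required = {"timestamp", "receiver_id", "tag_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        logger.warning("%s: no detection rows", path)
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
        return df[["timestamp", "receiver_id", "tag_id"]]
    df["timestamp"] = _parse_utc(df["timestamp"], "timestamp", path)
    known = set(receivers["receiver_id"])
    unknown = sorted(set(df["receiver_id"]) - known)
    if unknown:
        raise ValueError(f"{path}: detections reference unknown receiver(s) {unknown}")
    df = df.sort_values(DETECTION_SORT, kind="mergesort").reset_index(drop=True)
    logger.info("%s: read %d detections of %d tags", path, len(df), df["tag_id"].nunique())
    return df[["timestamp", "receiver_id", "tag_id"]]


def read_deployments(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal_id": str, "tag_id": str, "sex": str, "maturity": str})
    required = {"animal_id", "tag_id", "release_time", "sex", "wingspan_cm", "maturity", "satellite_tag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["release_time"] = _parse_utc(df["release_time"], "release_time", path)
    if (df["wingspan_cm"] <= 0).any():
        raise ValueError(f"{path}: wingspan_cm must be positive")
    if df["tag_id"].duplicated().any():
        raise ValueError(f"{path}: a tag may be deployed on only one animal")
    bad_sex = set(df["sex"]) - {"F", "M"}
    if bad_sex:
        raise ValueError(f"{path}: sex must be F or M, got {sorted(bad_sex)}")
    bad_mat = set(df["maturity"]) - {"immature", "mature"}
    if bad_mat:
        raise ValueError(f"{path}: maturity must be immature/mature, got {sorted(bad_mat)}")
    return df.sort_values("animal_id").reset_index(drop=True)


def read_environment(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"date", "chla", "moon_frac"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if df["date"].duplicated().any():
        raise ValueError(f"{path}: duplicate environment dates")
    if (df["chla"] < 0).any():
        raise ValueError(f"{path}: chla must be non-negative")
    if ((df["moon_frac"] < 0) | (df["moon_frac"] > 1)).any():
        raise ValueError(f"{path}: moon_frac must be in [0, 1]")
    df = df.sort_values("date").reset_index(drop=True)
    dates = pd.to_datetime(df["date"])
    gaps = dates.diff().dt.days.iloc[1:]
    if (gaps > 1).any():
        logger.warning("%s: gaps in daily environment series", path)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table deterministically (ISO timestamps, no index)."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def active_station_count(receivers: pd.DataFrame, when) -> int:
    """Number of receivers with an active interval covering the given instant."""
    ts = pd.Timestamp(when)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    mask = (receivers["active_start"] <= ts) & (ts < receivers["active_end"])
    return int(receivers.loc[mask, "receiver_id"].nunique())


def daily_active_station_counts(receivers: pd.DataFrame, dates) -> pd.Series:
    """Active receiver count per calendar date (evaluated at local noon)."""
    counts = {}
    for d in dates:
        ts = pd.Timestamp(d).tz_localize("UTC") + timedelta(hours=12)
        counts[d] = active_station_count(receivers, ts)
    return pd.Series(counts, name="n_stations")
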