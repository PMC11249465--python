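"""Data model and file IO for the telemetry pipeline.

Tabular data are held in :class:`pandas.DataFrame` objects with fixed schemas
(the idiom of movement-ecology toolkits), one row per telemetry fix,
deployment record, or hourly temperature record.

Fix columns
    ``tag_id, bear_id, time, lon, lat, source, loc_class, h_error_m,
    activity, on_land``

    * ``source`` is ``"argos"`` or ``"gps"``.
    * ``loc_class`` is one of the six Argos location classes ``3,2,1,0,A,B``
      (quality codes in decreasing order of accuracy) and is present iff
      ``source == "argos"``.
    * ``h_error_m`` is the GPS horizontal-error radius in metres, present iff
      ``source == "gps"``.
    * ``activity`` (``active``/``inactive``) and ``on_land`` may be missing.

Deployment columns
    ``tag_id, bear_id, design, attach_time, season, adhesive, fix_interval_h,
    end_time, end_cause`` where ``design`` is one of ``pentagon, seatrkr,
    tribrush, ear``.

Temperature columns
    ``station_id, station_lon, station_lat, time, temp_c`` — hourly records
    from one or more fixed weather stations.

Timestamps are UTC throughout; intervals are exact timestamp differences in
hours.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np
import pandas as pd

from .geo import great_circle_km

logger = logging.getLogger("beartrack")

ARGOS_CLASSES = ("3", "2", "1", "0", "A", "B")

#: Nominal horizontal-error upper bound (m) per Argos location class.  Classes
#: derived from >= 4 satellite messages (3,2,1,0) carry bounds; class 0 is
#: only bounded below (> 1500 m, represented as +inf) and classes A/B carry
#: no estimate at all (None).
ERROR_CLASS_BOUND_M: dict[str, float | None] = {
    "3": 250.0,
    "2": 500.0,
    "1": 1500.0,
    "0": math.inf,
    "A": None,
    "B": None,
}

TAG_DESIGNS = ("pentagon", "seatrkr", "tribrush", "ear")

FIX_COLUMNS = [
    "tag_id",
    "bear_id",
    "time",
    "lon",
    "lat",
    "source",
    "loc_class",
    "h_error_m",
    "activity",
    "on_land",
]

DEPLOYMENT_COLUMNS = [
    "tag_id",
    "bear_id",
    "design",
    "attach_time",
    "season",
    "adhesive",
    "fix_interval_h",
    "end_time",
    "end_cause",
]

TEMPERATURE_COLUMNS = ["station_id", "station_lon", "station_lat", "time", "temp_c"]


class SchemaError(ValueError):
    """A table is missing a required column or contains an invalid value."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing required column(s): {', '.join(missing)}")


def _parse_times(series: pd.Series, what: str) -> pd.Series:
    try:
        return pd.to_datetime(series, utc=True, format="ISO8601")
    except (ValueError, TypeError):
        pass
    # fall back row-by-row to report the offending row number
    out = pd.to_datetime(series, utc=True, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"{what}: unparseable timestamp at row {row}: {series.iloc[row]!r}")
    return out


def read_fixes(path) -> pd.DataFrame:
    """Read a fix table from a comma-delimited file.

    Rows are sorted by ``(tag_id, time)``; duplicate ``(tag_id, time)`` rows
    are collapsed to the first occurrence with a logged warning.  Raises
    :class:`SchemaError` for missing columns or unparseable values, naming
    the row.
    """
    df = pd.read_csv(path, dtype={"tag_id": str, "bear_id": str, "loc_class": str})
    required = ["tag_id", "bear_id", "time", "lon", "lat", "source"]
    _require_columns(df, required, "fixes")
    for col in FIX_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["time"] = _parse_times(df["time"], "fixes")
    df["on_land"] = _coerce_bool(df["on_land"])
    df = df[FIX_COLUMNS]
    validate_fixes(df)
    df = df.sort_values(["tag_id", "time"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(subset=["tag_id", "time"], keep="first")
    if dup.any():
        logger.warning("collapsed %d duplicate (tag_id, time) fix row(s), keeping first", int(dup.sum()))
        df = df.loc[~dup].reset_index(drop=True)
    return df


def _coerce_bool(series: pd.Series) -> pd.Series:
    def conv(v):
        if pd.isna(v):
            return np.nan
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in ("true", "1", "1.0", "t", "yes"):
            return True
        if s in ("false", "0", "0.0", "f", "no"):
            return False
        raise SchemaError(f"unparseable boolean value: {v!r}")

    return series.map(conv)


def validate_fixes(df: pd.DataFrame) -> None:
    """Check fix-table invariants, raising :class:`SchemaError` with a row number."""
    lat = df["lat"].to_numpy(dtype=float)
    lon = df["lon"].to_numpy(dtype=float)
    bad = np.flatnonzero((np.abs(lat) > 90.0) | (np.abs(lon) > 180.0) | ~np.isfinite(lat) | ~np.isfinite(lon))
    if bad.size:
        raise SchemaError(f"fixes: coordinate out of range at row {int(bad[0])}")
    src = df["source"].astype(str)
    bad_src = ~src.isin(["argos", "gps"])
    if bad_src.any():
        row = int(np.flatnonzero(bad_src.to_numpy())[0])
        raise SchemaError(f"fixes: unknown source {src.iloc[row]!r} at row {row}")
    is_argos = (src == "argos").to_numpy()
    lc = df["loc_class"]
    has_lc = lc.notna().to_numpy()
    bad_cls = has_lc & ~lc.astype(str).isin(ARGOS_CLASSES).to_numpy()
    if bad_cls.any():
        row = int(np.flatnonzero(bad_cls)[0])
        raise SchemaError(f"fixes: invalid Argos location class {lc.iloc[row]!r} at row {row}")
    mism = np.flatnonzero(is_argos != has_lc)
    if mism.size:
        raise SchemaError(
            f"fixes: loc_class must be present iff source=argos (violated at row {int(mism[0])})"
        )
    he = pd.to_numeric(df["h_error_m"], errors="coerce")
    has_he = he.notna().to_numpy()
    mism = np.flatnonzero(~is_argos != has_he)
    if mism.size:
        raise SchemaError(
            f"fixes: h_error_m must be present iff source=gps (violated at row {int(mism[0])})"
        )
    if (he.dropna() <= 0).any():
        row = int(np.flatnonzero(has_he & (he.to_numpy() <= 0))[0])
        raise SchemaError(f"fixes: h_error_m must be > 0 (violated at row {row})")
    act = df["activity"]
    bad_act = act.notna() & ~act.astype(str).isin(["active", "inactive"])
    if bad_act.any():
        row = int(np.flatnonzero(bad_act.to_numpy())[0])
        raise SchemaError(f"fixes: invalid activity value {act.iloc[row]!r} at row {row}")


def write_fixes(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["time"] = pd.to_datetime(out["time"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_deployments(path) -> pd.DataFrame:
    """Read a deployment table (one row per tag deployment).

    The same ``bear_id`` may appear under several ``tag_id`` values (bears
    re-tagged after an earlier tag stopped transmitting).
    """
    df = pd.read_csv(path, dtype={"tag_id": str, "bear_id": str})
    _require_columns(df, ["tag_id", "bear_id", "design", "attach_time", "fix_interval_h"], "deployments")
    for col in DEPLOYMENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["attach_time"] = _parse_times(df["attach_time"], "deployments")
    end = df["end_time"].replace("", np.nan)
    if end.notna().any():
        df["end_time"] = _parse_times(end, "deployments")
    else:
        df["end_time"] = pd.Series(pd.NaT, index=df.index, dtype="datetime64[ns, UTC]")
    df["adhesive"] = _coerce_bool(df["adhesive"]).fillna(False)
    bad = ~df["design"].astype(str).isin(TAG_DESIGNS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"deployments: unknown design {df['design'].iloc[row]!r} at row {row}")
    fi = pd.to_numeric(df["fix_interval_h"], errors="coerce")
    if (fi <= 0).any() or fi.isna().any():
        raise SchemaError("deployments: fix_interval_h must be a positive number")
    df["fix_interval_h"] = fi
    ok = df["end_time"].isna() | (df["end_time"] >= df["attach_time"])
    if not ok.all():
        row = int(np.flatnonzero((~ok).to_numpy())[0])
        raise SchemaError(f"deployments: end_time before attach_time at row {row}")
    return df[DEPLOYMENT_COLUMNS]


def write_deployments(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("attach_time", "end_time"):
        t = pd.to_datetime(out[col], utc=True)
        out[col] = t.dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_temperature(path) -> pd.DataFrame:
    """Read hourly station temperature records (possibly several stations)."""
    df = pd.read_csv(path, dtype={"station_id": str})
    _require_columns(df, TEMPERATURE_COLUMNS, "temperature")
    df["time"] = _parse_times(df["time"], "temperature")
    df = df.sort_values(["station_id", "time"], kind="mergesort").reset_index(drop=True)
    for sid, g in df.groupby("station_id"):
        dt = g["time"].diff().dropna()
        if (dt <= pd.Timedelta(0)).any():
            raise SchemaError(f"temperature: non-increasing timestamps for station {sid}")
    return df[TEMPERATURE_COLUMNS]


def write_temperature(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["time"] = pd.to_datetime(out["time"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def hours_between(t, t0) -> np.ndarray:
    """Exact timestamp differences in hours (vectorized)."""
    t = pd.to_datetime(t, utc=True)
    delta = (t - t0).to_numpy() if hasattr(t, "to_numpy") else np.asarray(t - t0)
    return delta.astype("timedelta64[ns]").astype(np.int64) / 3.6e12


def nearest_station(temperature: pd.DataFrame, lon: float, lat: float) -> pd.DataFrame:
    """Records of the station nearest (great-circle) to a point."""
    if temperature.empty:
        raise ValueError("temperature series is empty")
    stations = temperature[["station_id", "station_lon", "station_lat"]].drop_duplicates("station_id")
    d = great_circle_km(stations["station_lon"], stations["station_lat"], lon, lat)
    sid = stations["station_id"].iloc[int(np.argmin(np.atleast_1d(d)))]
    return temperature[temperature["station_id"] == sid]


def attach_temperature(track: pd.DataFrame, temperature: pd.DataFrame, max_gap_h: float = 6.0) -> pd.DataFrame:
    """Attach an ambient-temperature covariate to time-ordered positions.

    Each position takes the temperature of the record nearest in time within
    ``max_gap_h`` hours, linearly interpolated between bracketing records when
    both exist.  Positions with no record within ``max_gap_h`` are flagged
    ``temp_missing``; the covariate is never extrapolated beyond that window.

    When several stations are present the station nearest (great-circle) to
    the track's centroid is used.

    Returns a copy of ``track`` with ``temp_c`` and ``temp_missing`` columns.
    """
    if temperature.empty:
        raise ValueError("temperature series is empty")
    series = nearest_station(temperature, float(track["lon"].mean()), float(track["lat"].mean()))
    series = series.sort_values("time")
    t0 = series["time"].iloc[0]
    st = hours_between(series["time"], t0)
    sv = series["temp_c"].to_numpy(dtype=float)
    pt = hours_between(track["time"], t0)

    idx = np.searchsorted(st, pt)  # first record >= position time
    n = len(st)
    left = np.clip(idx - 1, 0, n - 1)
    right = np.clip(idx, 0, n - 1)
    dl = np.abs(pt - st[left])
    dr = np.abs(st[right] - pt)
    has_left = idx > 0
    has_right = idx < n
    dl = np.where(has_left, dl, np.inf)
    dr = np.where(has_right, dr, np.inf)
    nearest = np.minimum(dl, dr)
    missing = nearest > max_gap_h

    temp = np.full(len(pt), np.nan)
    both = has_left & has_right & ~missing
    span = np.where(both, st[right] - st[left], 1.0)
    w = np.where(span > 0, (pt - st[left]) / span, 0.0)
    temp[both] = (1 - w[both]) * sv[left[both]] + w[both] * sv[right[both]]
    one_sided = ~both & ~missing
    use_left = one_sided & (dl <= dr)
    use_right = one_sided & (dr < dl)
    temp[use_left] = sv[left[use_left]]
    temp[use_right] = sv[right[use_right]]

    out = track.copy()
    out["temp_c"] = temp
    out["temp_missing"] = missing
    return out
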