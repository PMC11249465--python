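"""Filtering and segmentation of raw telemetry fixes.

The sequence mirrors standard practice for Argos/GPS wildlife telemetry:

1. drop the first days after capture (post-immobilization behaviour),
2. remove biologically implausible locations with a McConnell-style
   root-mean-square speed filter (default threshold 40 km/h),
3. keep terrestrial locations, retaining short marine "forays" (< 50
   consecutive fixes) bounded by land fixes,
4. split tracks at temporal gaps > 24 h and discard segments with < 100
   fixes, which carry little information about behavioural switching.

All filters only remove rows; coordinates and timestamps are never altered,
and every filter is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import great_circle_km
from .core import hours_between

__all__ = [
    "TrackSegment",
    "truncate_post_capture",
    "speed_filter",
    "rms_speeds",
    "terrestrial_filter",
    "resolve_on_land",
    "segment_tracks",
]


@dataclass
class TrackSegment:
    """A time-ordered run of fixes for one deployment with no gap > 24 h."""

    tag_id: str
    segment_index: int
    fixes: pd.DataFrame
    source: str

    def __len__(self) -> int:
        return len(self.fixes)


def truncate_post_capture(fixes: pd.DataFrame, deployment: pd.Series, days: float = 3.0) -> pd.DataFrame:
    """Drop fixes within ``days`` (default 3) of the deployment's attach time.

    A fix exactly at the boundary (attach + 72 h) is retained.
    """
    if fixes.empty:
        return fixes
    h = hours_between(fixes["time"], deployment["attach_time"])
    return fixes.loc[h >= days * 24.0].reset_index(drop=True)


def rms_speeds(lon: np.ndarray, lat: np.ndarray, th: np.ndarray) -> np.ndarray:
    """Root-mean-square speed (km/h) of each fix against its two preceding and
    two following neighbours (McConnell construction); endpoints use the
    neighbours that exist.
    """
    n = len(lon)
    out = np.zeros(n)
    for i in range(n):
        sq = []
        for j in (i - 2, i - 1, i + 1, i + 2):
            if 0 <= j < n:
                dt = abs(th[i] - th[j])
                if dt <= 0:
                    sq.append(np.inf)
                else:
                    d = great_circle_km(lon[i], lat[i], lon[j], lat[j])
                    sq.append((d / dt) ** 2)
        out[i] = np.sqrt(np.mean(sq)) if sq else 0.0
    return out


def speed_filter(
    fixes: pd.DataFrame, vmax_kmh: float = 40.0, mode: str = "rms"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iteratively remove implausibly fast fixes; returns (retained, removed).

    ``mode="rms"`` (default): while any interior fix has RMS speed against its
    retained neighbours >= ``vmax_kmh``, remove the fix with the largest RMS
    speed (ties broken by earliest time).  The first and last fixes are never
    removed.  The result is idempotent: filtering retained output again
    changes nothing.

    ``mode="pairwise"``: simpler sensitivity variant that removes a fix when
    the speed from its retained predecessor is >= ``vmax_kmh``.
    """
    if len(fixes) < 2:
        return fixes.reset_index(drop=True), fixes.iloc[0:0]
    lon = fixes["lon"].to_numpy(dtype=float)
    lat = fixes["lat"].to_numpy(dtype=float)
    th = hours_between(fixes["time"], fixes["time"].iloc[0])
    n = len(fixes)
    keep = np.ones(n, dtype=bool)

    if mode == "pairwise":
        prev = 0
        for i in range(1, n):
            dt = th[i] - th[prev]
            d = great_circle_km(lon[prev], lat[prev], lon[i], lat[i])
            if dt > 0 and d / dt >= vmax_kmh:
                keep[i] = False
            else:
                prev = i
    elif mode == "rms":
        while True:
            idx = np.flatnonzero(keep)
            if idx.size < 3:
                break
            v = rms_speeds(lon[idx], lat[idx], th[idx])
            v[0] = 0.0  # endpoints are never removed
            v[-1] = 0.0
            worst = int(np.argmax(v))  # argmax takes the first max -> earliest time
            if v[worst] < vmax_kmh:
                break
            keep[idx[worst]] = False
    else:
        raise ValueError(f"unknown speed-filter mode: {mode!r}")

    retained = fixes.loc[keep].reset_index(drop=True)
    removed = fixes.loc[~keep].reset_index(drop=True)
    return retained, removed


def resolve_on_land(fixes: pd.DataFrame, land_polygon=None) -> np.ndarray:
    """Resolve a boolean on-land value per fix.

    Priority: the per-fix ``on_land`` flag where present, else point-in-polygon
    against ``land_polygon`` (a shapely geometry in lon/lat).  Raises if
    neither source can resolve a fix.
    """
    flag = fixes["on_land"]
    out = np.empty(len(fixes), dtype=object)
    out[:] = [None if pd.isna(v) else bool(v) for v in flag]
    unresolved = [i for i, v in enumerate(out) if v is None]
    if unresolved:
        if land_polygon is None:
            raise ValueError(
                f"{len(unresolved)} fix(es) lack an on_land flag and no land polygon was supplied"
            )
        from shapely.geometry import Point

        for i in unresolved:
            out[i] = land_polygon.contains(Point(fixes["lon"].iloc[i], fixes["lat"].iloc[i]))
    return out.astype(bool)


def terrestrial_filter(
    fixes: pd.DataFrame, max_foray: int = 50, land_polygon=None
) -> pd.DataFrame:
    """Keep terrestrial fixes plus bounded marine forays, per deployment.

    Land fixes are always retained.  A maximal run of consecutive marine fixes
    is retained iff it is shorter than ``max_foray`` fixes AND it is bounded
    by land fixes of the same deployment on both sides (the bear returned to
    land).  Leading/trailing marine runs and runs of length >= ``max_foray``
    are removed.
    """
    if fixes.empty:
        return fixes
    parts = []
    for _, g in fixes.groupby("tag_id", sort=False):
        land = resolve_on_land(g, land_polygon)
        keep = land.copy()
        n = len(g)
        i = 0
        while i < n:
            if land[i]:
                i += 1
                continue
            j = i
            while j < n and not land[j]:
                j += 1
            run_len = j - i
            bounded = i > 0 and j < n  # land on both sides within this deployment
            if bounded and run_len < max_foray:
                keep[i:j] = True
            i = j
        parts.append(g.loc[keep])
    return pd.concat(parts).reset_index(drop=True) if parts else fixes.iloc[0:0]


def segment_tracks(
    fixes: pd.DataFrame, gap_h: float = 24.0, min_len: int = 100
) -> tuple[list[TrackSegment], int]:
    """Split each tag's fixes at temporal gaps strictly greater than ``gap_h``.

    A gap of exactly ``gap_h`` hours does not split.  Segments with fewer than
    ``min_len`` fixes are discarded; the second return value is the number of
    fixes discarded that way (for the report's stage accounting).
    """
    segments: list[TrackSegment] = []
    n_discarded = 0
    for tag_id, g in fixes.groupby("tag_id", sort=False):
        g = g.reset_index(drop=True)
        if g.empty:
            continue
        th = hours_between(g["time"], g["time"].iloc[0])
        breaks = np.flatnonzero(np.diff(th) > gap_h) + 1
        seg_index = 0
        for chunk in np.split(np.arange(len(g)), breaks):
            sub = g.iloc[chunk].reset_index(drop=True)
            if len(sub) < min_len:
                n_discarded += len(sub)
                continue
            source = str(sub["source"].iloc[0])
            segments.append(TrackSegment(str(tag_id), seg_index, sub, source))
            seg_index += 1
    return segments, n_discarded
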