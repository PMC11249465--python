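"""Tag-performance summaries: functional duration and Argos error classes.

A tag's functional duration is the number of days it remained active while
attached: transmission ends either because the tag detached (the transmitter
enters inactivity mode after >= 12 h without movement and sends a run of
inactivity-flagged fixes) or because it stopped (malfunction or battery
exhaustion).  A run of more than three consecutive inactive fixes is read as
detachment, dated to the first fix of the run.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import ARGOS_CLASSES, hours_between

logger = logging.getLogger("beartrack")

__all__ = [
    "detect_detachment",
    "functional_duration",
    "summarize_durations",
    "error_class_table",
    "gps_error_summary",
]

#: minimum run of consecutive inactivity-flagged fixes read as detachment
#: ("> 3 consecutive fixes", i.e. at least 4)
MIN_INACTIVE_RUN = 4


def detect_detachment(fixes: pd.DataFrame) -> tuple[str, pd.Timestamp | None]:
    """Classify the end of one tag's record as detachment or stoppage.

    Returns ``("detached", first_fix_of_inactive_run)`` when a run of at
    least :data:`MIN_INACTIVE_RUN` consecutive inactive fixes exists,
    otherwise ``("stopped", last_transmission_time)``.
    """
    if fixes.empty:
        return "stopped", None
    act = fixes["activity"].to_numpy(dtype=object)
    inactive = np.array([(not pd.isna(a)) and str(a) == "inactive" for a in act])
    run = 0
    for i, flag in enumerate(inactive):
        if flag:
            run += 1
            if run >= MIN_INACTIVE_RUN:
                start = i - run + 1
                return "detached", fixes["time"].iloc[start]
        else:
            run = 0
    return "stopped", fixes["time"].iloc[-1]


def functional_duration(deployment: pd.Series, fixes: pd.DataFrame) -> float:
    """Days the tag was active on the bear: end event minus attach time.

    The end event is the detachment time when detected, else the last
    transmission.  Returns real-valued days; 0 (with a warning) when the tag
    produced no fixes.
    """
    if fixes.empty:
        logger.warning("tag %s has no fixes; functional duration set to 0", deployment["tag_id"])
        return 0.0
    status, event_time = detect_detachment(fixes)
    days = float(hours_between(pd.Series([event_time]), deployment["attach_time"])[0]) / 24.0
    return max(days, 0.0)


def summarize_durations(durations: pd.DataFrame) -> pd.DataFrame:
    """Per-design duration summary: n, mean, min, max, SE of the mean.

    ``durations`` needs columns ``design`` and ``duration_days``.  SE uses
    the n-1 sample SD divided by sqrt(n) and is absent (NaN) for n < 2.
    Output is invariant to input row order.
    """
    rows = []
    for design, g in durations.groupby("design", sort=True):
        d = g["duration_days"].to_numpy(dtype=float)
        se = float(np.std(d, ddof=1) / np.sqrt(len(d))) if len(d) > 1 else np.nan
        rows.append(
            {
                "design": design,
                "n": len(d),
                "mean_days": float(np.mean(d)),
                "min_days": float(np.min(d)),
                "max_days": float(np.max(d)),
                "se_days": se,
            }
        )
    return pd.DataFrame(rows)


def error_class_table(fixes: pd.DataFrame, deployments: pd.DataFrame) -> pd.DataFrame:
    """Proportion of Argos fixes in each location class, per tag design.

    GPS fixes are excluded (summarize them with :func:`gps_error_summary`).
    Designs with zero Argos fixes are omitted with a log note.  Rows sum
    to 1.
    """
    design_of = deployments.set_index("tag_id")["design"]
    argos = fixes[fixes["source"] == "argos"].copy()
    argos["design"] = argos["tag_id"].map(design_of)
    rows = []
    for design in deployments["design"].unique():
        sub = argos[argos["design"] == design]
        if sub.empty:
            logger.info("design %s has no Argos fixes; omitted from error-class table", design)
            continue
        counts = sub["loc_class"].astype(str).value_counts()
        total = counts.sum()
        row = {"design": design}
        for cls in ARGOS_CLASSES:
            row[f"class_{cls}"] = counts.get(cls, 0) / total
        rows.append(row)
    return pd.DataFrame(rows)


def gps_error_summary(fixes: pd.DataFrame) -> dict:
    """Mean/min/max horizontal error (m) over GPS fixes."""
    he = pd.to_numeric(fixes.loc[fixes["source"] == "gps", "h_error_m"], errors="coerce").dropna()
    if he.empty:
        return {"n": 0, "mean_m": np.nan, "min_m": np.nan, "max_m": np.nan}
    return {
        "n": int(len(he)),
        "mean_m": float(he.mean()),
        "min_m": float(he.min()),
        "max_m": float(he.max()),
    }
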