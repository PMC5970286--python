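"""Panel construction: day-level and acute-window alignment.

Two analysis panels are built from the filtered streams:

* the **day panel** — one row per valid participant-day with at least one
  urge report: daily steps (full calendar day) and mean daily urge;
* the **window panel** — one row per urge report on a valid day, with steps
  accumulated over the 5/30/60/120-minute lookback windows ending at the
  report, plus the HR-presence coverage of each lookback.

Lookbacks are half-open ``[t - w, t)`` where ``t`` is the report timestamp
truncated to its minute: the minute containing the report is excluded so
contemporaneous movement (walking while texting) cannot contaminate the
exposure. Coverage is the fraction of lookback minutes with HR present;
model fits drop observations whose coverage for the analyzed window falls
below a threshold (default 0.8).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

from .streams import ParticipantStream, stream_from_minutes

logger = logging.getLogger(__name__)

ACUTE_WINDOWS = (5, 30, 60, 120)
COVERAGE_THRESHOLD = 0.8


def accumulate_window_steps(
    stream: ParticipantStream | pd.DataFrame,
    event_time: datetime | pd.Timestamp,
    window_minutes: int,
) -> tuple[int, float]:
    """Steps and HR coverage over the ``window_minutes`` lookback before an event.

    Sums steps over minutes starting in ``[t - w, t)`` with ``t`` the event
    timestamp truncated to its minute. Coverage is the hr_present fraction
    over those ``w`` minutes; minutes before the stream start count as
    uncovered, and an event at or before the stream start yields coverage 0.
    """
    if not isinstance(stream, ParticipantStream):
        stream = stream_from_minutes("_", stream)
    t = stream.minute_index(pd.Timestamp(event_time).to_pydatetime())
    lo, hi = t - window_minutes, t
    if hi <= 0:
        return 0, 0.0
    lo_c = max(lo, 0)
    hi_c = min(hi, stream.steps.size)
    steps = int(stream.steps[lo_c:hi_c].sum())
    covered = int(stream.hr_present[lo_c:hi_c].sum())
    return steps, covered / window_minutes


def build_day_panel(day_records: pd.DataFrame) -> pd.DataFrame:
    """Unbalanced day-level panel: valid days with at least one urge report.

    Mean daily urge is undefined on days without reports, so such days drop
    out. Output is sorted by (participant, date) regardless of input order.
    """
    panel = day_records.loc[
        day_records["valid"] & (day_records["n_urges"] > 0),
        ["participant", "date", "daily_steps", "mean_urge", "n_urges"],
    ]
    return panel.sort_values(["participant", "date"], kind="mergesort").reset_index(drop=True)


def build_window_panel(
    streams: dict[str, ParticipantStream],
    urges: pd.DataFrame,
    day_records: pd.DataFrame,
    windows: tuple[int, ...] = ACUTE_WINDOWS,
) -> pd.DataFrame:
    """Acute-window panel: one row per urge report on a valid day.

    Columns: participant, timestamp, urge, prompted, steps_<w> and
    coverage_<w> for each lookback. Coverage-based retention is applied by
    the model fit for its own window, not here, so one panel serves all
    window lengths.
    """
    valid_days = {
        (r.participant, pd.Timestamp(r.date))
        for r in day_records.loc[day_records["valid"]].itertuples()
    }
    rows = []
    urges = urges.sort_values(["participant", "timestamp"], kind="mergesort")
    for pid, grp in urges.groupby("participant", sort=True):
        stream = streams.get(pid)
        if stream is None:
            continue
        ts = pd.to_datetime(grp["timestamp"])
        keep = np.array([(pid, t.normalize()) in valid_days for t in ts])
        if not keep.any():
            continue
        grp = grp[keep]
        ts = ts[keep]
        # cumulative sums give every lookback in O(1) per event
        cs = np.concatenate(([0], np.cumsum(stream.steps)))
        ch = np.concatenate(([0], np.cumsum(stream.hr_present)))
        origin = pd.Timestamp(stream.start)
        t_idx = ((ts - origin).dt.total_seconds() // 60).astype(int).to_numpy()
        rec = {
            "participant": pid,
            "timestamp": ts.to_numpy(),
            "urge": grp["urge"].to_numpy(),
            "prompted": grp.get("prompted", pd.Series(False, index=grp.index)).to_numpy(),
        }
        for w in windows:
            lo = np.clip(t_idx - w, 0, cs.size - 1)
            hi = np.clip(t_idx, 0, cs.size - 1)
            rec[f"steps_{w}"] = cs[hi] - cs[lo]
            rec[f"coverage_{w}"] = (ch[hi] - ch[lo]) / w
        rows.append(pd.DataFrame(rec))
    if not rows:
        cols = ["participant", "timestamp", "urge", "prompted"]
        cols += [f"steps_{w}" for w in windows] + [f"coverage_{w}" for w in windows]
        return pd.DataFrame(columns=cols)
    panel = pd.concat(rows, ignore_index=True)
    return panel.sort_values(["participant", "timestamp"], kind="mergesort").reset_index(drop=True)


@dataclass
class MidpointSummary:
    participant: str
    midpoint_date: object
    pre_mean_urge: float
    post_mean_urge: float
    pre_mean_steps: float
    post_mean_steps: float


def split_midpoint(day_records: pd.DataFrame) -> MidpointSummary | None:
    """Pre/post means around the day at which participation was 50% complete.

    Only valid days count. With n valid days the midpoint is the
    (floor(n/2)+1)-th valid day; "pre" is every valid day before it and
    "post" is the midpoint day onward, so a 4-day record splits 2/2.
    Returns None (with a warning) below 2 valid days.
    """
    days = day_records.loc[day_records["valid"]].sort_values("date")
    n = len(days)
    if n < 2:
        logger.warning(
            "participant %s has %d valid day(s); midpoint split skipped",
            day_records["participant"].iloc[0] if len(day_records) else "?",
            n,
        )
        return None
    k = n // 2  # pre gets the first floor(n/2) days
    pre, post = days.iloc[:k], days.iloc[k:]
    return MidpointSummary(
        participant=days["participant"].iloc[0],
        midpoint_date=post["date"].iloc[0],
        pre_mean_urge=float(pre["mean_urge"].mean()),
        post_mean_urge=float(post["mean_urge"].mean()),
        pre_mean_steps=float(pre["daily_steps"].mean()),
        post_mean_steps=float(post["daily_steps"].mean()),
    )


def flag_outliers(values) -> np.ndarray:
    """Tukey fences: flag values beyond 1.5 IQR outside the quartiles.

    Quartiles use numpy's linear-interpolation convention. Fewer than 4
    values → nothing is flagged (a warning is issued): quartiles of so few
    points are not meaningful.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        warnings.warn("fewer than 4 values; no outliers flagged", stacklevel=2)
        return np.zeros(arr.size, dtype=bool)
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    iqr = q3 - q1
    return (arr > q3 + 1.5 * iqr) | (arr < q1 - 1.5 * iqr)


def baseline_followup_change(
    baseline: pd.DataFrame, followup: pd.DataFrame, column: str = "cigs_per_day"
) -> tuple[pd.DataFrame, dict]:
    """Per-participant change in daily cigarette consumption and its summary.

    Change is follow-up minus baseline. Participants missing from follow-up
    are excluded and counted in the attrition report.
    """
    merged = baseline[["participant", column]].merge(
        followup[["participant", column]],
        on="participant",
        how="left",
        suffixes=("_baseline", "_followup"),
        validate="one_to_one",
    )
    missing = merged[f"{column}_followup"].isna()
    if missing.all():
        raise ValueError("no participants have both baseline and follow-up values")
    changes = merged.loc[~missing].copy()
    changes["change"] = changes[f"{column}_followup"] - changes[f"{column}_baseline"]
    summary = {
        "mean_change": float(changes["change"].mean()),
        "sd_change": float(changes["change"].std(ddof=1)) if len(changes) > 1 else float("nan"),
        "n": int(len(changes)),
        "n_missing_followup": int(missing.sum()),
    }
    return changes[["participant", "change"]].reset_index(drop=True), summary
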