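"""Wear-time classification from heart-rate presence.

The device's optical HR sensor samples continuously while worn, so the
presence of HR data in a minute is taken as evidence of wear. Nonwear is a
maximal run of at least 90 consecutive minutes with no HR data inside the
10:00-22:00 target window (participants were not asked to wear the device
overnight). A day is valid when it has fewer than two such nonwear windows
and at least six hours (360 minutes) of wear inside the target window;
participants need at least 42 valid days (six weeks, in any arrangement)
to enter the analysis.

Conventions, stated once and used everywhere:

* the target window is half-open, ``[10:00, 22:00)`` — exactly 720 minutes;
* minutes absent from a sparse export count as missing HR (device off);
* a gap is clipped to the target window *before* the >=90-minute test, so a
  gap running 08:30-11:30 contributes only its 10:00-11:30 portion;
* one long gap is one nonwear window (maximal runs, not overlapping 90-min
  placements) — otherwise any 180-minute gap would auto-exclude the day,
  defeating the single-window tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .streams import MINUTES_PER_DAY, ParticipantStream, stream_from_minutes

TARGET_START_MINUTE = 10 * 60
TARGET_END_MINUTE = 22 * 60
TARGET_WIDTH = TARGET_END_MINUTE - TARGET_START_MINUTE  # 720
NONWEAR_GAP_MINUTES = 90
MIN_WEAR_MINUTES = 6 * 60
MAX_NONWEAR_WINDOWS = 1
MIN_VALID_DAYS = 42


@dataclass(frozen=True)
class NonwearWindow:
    """Maximal missing-HR run inside the target window; ``end`` exclusive."""

    start: datetime
    end: datetime

    @property
    def duration(self) -> int:
        return int((self.end - self.start).total_seconds() // 60)


@dataclass
class DayRecord:
    participant: str
    date: date
    wear_minutes: int
    nonwear_windows: int
    valid: bool
    daily_steps: int
    mean_urge: float  # NaN when n_urges == 0
    n_urges: int


def _true_runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and lengths of maximal True runs in a 1-D bool array."""
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return starts, ends - starts


def _day_arrays(
    minutes: ParticipantStream | pd.DataFrame, day: date
) -> tuple[np.ndarray, np.ndarray]:
    """(steps, hr_present) for one calendar day on a dense 1440-minute grid."""
    if isinstance(minutes, ParticipantStream):
        sl = minutes.day_slice(day)
        return minutes.steps[sl], minutes.hr_present[sl]
    stream = stream_from_minutes("_", minutes, start=day, n_days=1)
    return stream.steps, stream.hr_present


def find_nonwear_windows(
    minutes: ParticipantStream | pd.DataFrame,
    day: date,
    min_gap_minutes: int = NONWEAR_GAP_MINUTES,
    target_window: tuple[int, int] = (TARGET_START_MINUTE, TARGET_END_MINUTE),
) -> list[NonwearWindow]:
    """All maximal runs of >= ``min_gap_minutes`` missing-HR minutes in the
    target window of ``day``.

    ``minutes`` may be a dense :class:`ParticipantStream` or a long-format
    minute table (sorted, unique per minute; absent minutes = missing HR).
    """
    lo, hi = target_window
    _, hr = _day_arrays(minutes, day)
    missing = ~hr[lo:hi]
    starts, lengths = _true_runs(missing)
    midnight = datetime.combine(day, datetime.min.time())
    out = []
    for s, ln in zip(starts, lengths):
        if ln >= min_gap_minutes:
            t0 = midnight + timedelta(minutes=int(lo + s))
            out.append(NonwearWindow(t0, t0 + timedelta(minutes=int(ln))))
    return out


def classify_day(
    minutes: ParticipantStream | pd.DataFrame,
    urges: pd.DataFrame | None,
    day: date,
    participant: str = "",
    min_gap_minutes: int = NONWEAR_GAP_MINUTES,
    min_wear_minutes: int = MIN_WEAR_MINUTES,
    max_nonwear_windows: int = MAX_NONWEAR_WINDOWS,
    target_window: tuple[int, int] = (TARGET_START_MINUTE, TARGET_END_MINUTE),
) -> DayRecord:
    """Aggregate one participant-day: wear minutes, nonwear windows,
    validity, daily steps and mean urge.

    ``daily_steps`` sums the full calendar day; wear accounting is confined
    to the target window. An empty day yields an invalid record with zero
    wear. ``urges`` (timestamp, urge) may be None.
    """
    lo, hi = target_window
    steps, hr = _day_arrays(minutes, day)
    if isinstance(minutes, ParticipantStream) and not participant:
        participant = minutes.participant_id
    wear = int(hr[lo:hi].sum())
    n_windows = len(find_nonwear_windows(minutes, day, min_gap_minutes, target_window))
    valid = n_windows <= max_nonwear_windows and wear >= min_wear_minutes
    if urges is not None and len(urges):
        ts = pd.to_datetime(urges["timestamp"])
        day_vals = urges.loc[ts.dt.date == day, "urge"].to_numpy()
    else:
        day_vals = np.array([])
    mean_urge = float(day_vals.mean()) if day_vals.size else float("nan")
    return DayRecord(
        participant=participant,
        date=day,
        wear_minutes=wear,
        nonwear_windows=n_windows,
        valid=bool(valid),
        daily_steps=int(steps.sum()),
        mean_urge=mean_urge,
        n_urges=int(day_vals.size),
    )


def classify_days(
    stream: ParticipantStream,
    urges: pd.DataFrame | None = None,
    min_gap_minutes: int = NONWEAR_GAP_MINUTES,
    min_wear_minutes: int = MIN_WEAR_MINUTES,
    max_nonwear_windows: int = MAX_NONWEAR_WINDOWS,
    target_window: tuple[int, int] = (TARGET_START_MINUTE, TARGET_END_MINUTE),
) -> pd.DataFrame:
    """Vectorized :func:`classify_day` over every day of a stream.

    Returns one row per day with the DayRecord columns; equivalent to the
    per-day function (asserted in the test suite) but linear-time over the
    whole stream.
    """
    lo, hi = target_window
    n_days = stream.n_days
    hr = stream.hr_present.reshape(n_days, MINUTES_PER_DAY)[:, lo:hi]
    steps = stream.steps.reshape(n_days, MINUTES_PER_DAY)
    wear = hr.sum(axis=1).astype(int)
    daily_steps = steps.sum(axis=1).astype(int)

    # Count maximal missing runs >= threshold per day: flatten the per-day
    # missing masks with a sentinel wear-minute between days so runs never
    # bridge a day boundary.
    missing = ~hr
    sep = np.zeros((n_days, 1), dtype=bool)
    flat = np.concatenate([missing, sep], axis=1).ravel()
    starts, lengths = _true_runs(flat)
    qualifying = lengths >= min_gap_minutes
    day_of_run = starts[qualifying] // (hi - lo + 1)
    n_windows = np.bincount(day_of_run, minlength=n_days).astype(int)

    valid = (n_windows <= max_nonwear_windows) & (wear >= min_wear_minutes)

    mean_urge = np.full(n_days, np.nan)
    n_urges = np.zeros(n_days, dtype=int)
    if urges is not None and len(urges):
        ts = pd.to_datetime(urges["timestamp"])
        offset = (ts.dt.normalize() - pd.Timestamp(stream.start)).dt.days.to_numpy()
        vals = urges["urge"].to_numpy(dtype=float)
        in_range = (offset >= 0) & (offset < n_days)
        sums = np.bincount(offset[in_range], weights=vals[in_range], minlength=n_days)
        counts = np.bincount(offset[in_range], minlength=n_days)
        n_urges = counts.astype(int)
        with np.errstate(invalid="ignore"):
            mean_urge = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    return pd.DataFrame(
        {
            "participant": stream.participant_id,
            "date": stream.days,
            "wear_minutes": wear,
            "nonwear_windows": n_windows,
            "valid": valid,
            "daily_steps": daily_steps,
            "mean_urge": mean_urge,
            "n_urges": n_urges,
        }
    )


def eligible_participants(
    day_records: pd.DataFrame, min_valid_days: int = MIN_VALID_DAYS
) -> set[str]:
    """Participants with at least ``min_valid_days`` valid days (any arrangement)."""
    counts = day_records.groupby("participant")["valid"].sum()
    return set(counts.index[counts >= min_valid_days])
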