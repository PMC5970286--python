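"""Minute-level participant streams.

A :class:`ParticipantStream` holds one participant's wearable record on a
dense per-minute grid: step counts and a heart-rate-presence flag for every
minute of every study day. Heart-rate *presence* (not magnitude) is the
wear-time signal downstream, so the stream never stores HR values.

Streams are timezone-naive local time with no DST transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440


@dataclass
class ParticipantStream:
    """Dense minute grid for one participant.

    Parameters
    ----------
    participant_id : str
        Stable identifier, unique within a cohort.
    start : datetime.date
        First study day (grid minute 0 is ``start`` at 00:00).
    steps : ndarray of int, shape (n_days * 1440,)
        Step count per minute; nonnegative.
    hr_present : ndarray of bool, shape (n_days * 1440,)
        True where at least one heart-rate sample was observed that minute.
    """

    participant_id: str
    start: date
    steps: np.ndarray
    hr_present: np.ndarray

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps)
        self.hr_present = np.asarray(self.hr_present, dtype=bool)
        if self.steps.shape != self.hr_present.shape:
            raise ValueError("steps and hr_present must have equal length")
        if self.steps.size % MINUTES_PER_DAY != 0:
            raise ValueError("stream length must be a whole number of days")
        if (self.steps < 0).any():
            raise ValueError("negative step counts")

    @property
    def n_days(self) -> int:
        return self.steps.size // MINUTES_PER_DAY

    @property
    def days(self) -> list[date]:
        return [self.start + timedelta(days=d) for d in range(self.n_days)]

    def minute_index(self, ts: datetime) -> int:
        """Absolute grid index of the minute containing ``ts`` (may be out of range)."""
        delta = ts.replace(second=0, microsecond=0) - datetime.combine(self.start, datetime.min.time())
        return int(delta.total_seconds() // 60)

    def day_slice(self, day: date) -> slice:
        offset = (day - self.start).days
        if not 0 <= offset < self.n_days:
            raise KeyError(f"day {day} outside stream range")
        return slice(offset * MINUTES_PER_DAY, (offset + 1) * MINUTES_PER_DAY)

    def to_minutes_frame(self, drop_absent: bool = False) -> pd.DataFrame:
        """Long-format minute table (timestamp, steps, hr_present).

        With ``drop_absent`` minutes lacking both steps and HR are omitted,
        matching device exports that skip idle minutes.
        """
        ts = pd.date_range(
            datetime.combine(self.start, datetime.min.time()),
            periods=self.steps.size,
            freq="min",
        )
        frame = pd.DataFrame(
            {"timestamp": ts, "steps": self.steps, "hr_present": self.hr_present}
        )
        if drop_absent:
            frame = frame[(frame["steps"] > 0) | frame["hr_present"]].reset_index(drop=True)
        return frame


def stream_from_minutes(
    participant_id: str, minutes: pd.DataFrame, start: date | None = None, n_days: int | None = None
) -> ParticipantStream:
    """Densify a long-format minute table into a :class:`ParticipantStream`.

    Absent minutes are treated as zero steps with missing HR (device off),
    not as data errors. Rows must be unique per minute and sorted.
    """
    ts = pd.to_datetime(minutes["timestamp"])
    if ts.dt.floor("min").duplicated().any():
        raise ValueError("duplicate minute records")
    if not ts.is_monotonic_increasing:
        raise ValueError("minute records out of order")
    if start is None:
        start = ts.iloc[0].date() if len(ts) else date(2000, 1, 1)
    if n_days is None:
        last = ts.iloc[-1].date() if len(ts) else start
        n_days = (last - start).days + 1
    steps = np.zeros(n_days * MINUTES_PER_DAY, dtype=np.int64)
    hr = np.zeros(n_days * MINUTES_PER_DAY, dtype=bool)
    if len(ts):
        origin = datetime.combine(start, datetime.min.time())
        idx = ((ts.dt.floor("min") - origin).dt.total_seconds() // 60).astype(int).to_numpy()
        keep = (idx >= 0) & (idx < steps.size)
        steps[idx[keep]] = minutes["steps"].to_numpy()[keep]
        if "hr_present" in minutes:
            hr[idx[keep]] = minutes["hr_present"].to_numpy()[keep].astype(bool)
    return ParticipantStream(participant_id, start, steps, hr)
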