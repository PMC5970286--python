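"""CSV readers and writers for the pipeline's interchange dialects.

All interchange is plain CSV with ISO-8601 local timestamps (no timezone
suffix), mirroring common wearable-platform exports:

* minute steps — columns ``Id, ActivityMinute, Steps``, idle minutes may
  be omitted;
* heart rate — columns ``Id, Time, Value``, one row per HR sample; only
  per-minute *presence* is retained;
* urges — columns ``Id, Timestamp, Urge, Prompted``;
* covariates — ``participant`` plus baseline fields.

Readers validate and reject malformed rows (with the offending row number)
rather than silently coercing them.
"""

from __future__ import annotations

import warnings
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .streams import MINUTES_PER_DAY, ParticipantStream
from .synth import Cohort

MODERATOR_COLUMNS = ["age", "sex_male", "race_nonwhite", "cigs_per_day", "ipaq_high", "quit_intent_yes"]


class DataError(ValueError):
    """Malformed input data; the message carries the row number."""


def _parse_timestamps(raw: pd.Series, what: str) -> pd.Series:
    ts = pd.to_datetime(raw, format="mixed", errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise DataError(f"malformed {what} timestamp at data row {row + 1}: {raw.iloc[row]!r}")
    return ts


def read_minute_steps(path) -> pd.DataFrame:
    """Minute step counts -> columns (participant, timestamp, steps), sorted."""
    raw = pd.read_csv(path, dtype={"Id": str})
    for col in ("Id", "ActivityMinute", "Steps"):
        if col not in raw.columns:
            raise DataError(f"steps file lacks required column {col!r}")
    ts = _parse_timestamps(raw["ActivityMinute"], "ActivityMinute")
    steps = pd.to_numeric(raw["Steps"], errors="coerce")
    if steps.isna().any() or (steps < 0).any():
        bad = steps.isna() | (steps < 0)
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataError(f"invalid step count at data row {row + 1}: {raw['Steps'].iloc[row]!r}")
    out = pd.DataFrame(
        {"participant": raw["Id"], "timestamp": ts.dt.floor("min"), "steps": steps.astype(int)}
    )
    dup = out.duplicated(subset=["participant", "timestamp"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise DataError(f"duplicate minute at data row {row + 1}")
    return out.sort_values(["participant", "timestamp"], kind="mergesort").reset_index(drop=True)


def read_heart_rate(path) -> pd.DataFrame:
    """HR samples -> per-minute presence flags (participant, timestamp, hr_present).

    A minute is flagged present when at least one sample lands in it.
    """
    raw = pd.read_csv(path, dtype={"Id": str})
    for col in ("Id", "Time", "Value"):
        if col not in raw.columns:
            raise DataError(f"heart-rate file lacks required column {col!r}")
    if raw.empty:
        return pd.DataFrame(columns=["participant", "timestamp", "hr_present"])
    ts = _parse_timestamps(raw["Time"], "Time")
    vals = pd.to_numeric(raw["Value"], errors="coerce")
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna().to_numpy())[0])
        raise DataError(f"invalid HR value at data row {row + 1}: {raw['Value'].iloc[row]!r}")
    out = pd.DataFrame({"participant": raw["Id"], "timestamp": ts.dt.floor("min")})
    out = out.drop_duplicates().sort_values(["participant", "timestamp"], kind="mergesort")
    out["hr_present"] = True
    return out.reset_index(drop=True)


def read_urges(path) -> pd.DataFrame:
    """Urge reports -> (participant, timestamp, urge, prompted); urge must be 1-9."""
    raw = pd.read_csv(path, dtype={"Id": str})
    for col in ("Id", "Timestamp", "Urge"):
        if col not in raw.columns:
            raise DataError(f"urge file lacks required column {col!r}")
    ts = _parse_timestamps(raw["Timestamp"], "Timestamp")
    urge = pd.to_numeric(raw["Urge"], errors="coerce")
    bad = urge.isna() | (urge != urge.round()) | (urge < 1) | (urge > 9)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataError(f"urge outside 1-9 at data row {row + 1}: {raw['Urge'].iloc[row]!r}")
    prompted = raw["Prompted"].astype(bool) if "Prompted" in raw.columns else False
    out = pd.DataFrame(
        {"participant": raw["Id"], "timestamp": ts, "urge": urge.astype(int), "prompted": prompted}
    )
    return out.sort_values(["participant", "timestamp"], kind="mergesort").reset_index(drop=True)


def read_covariates(path) -> pd.DataFrame:
    """Baseline (or follow-up) covariate table keyed by ``participant``."""
    raw = pd.read_csv(path)
    if "participant" not in raw.columns:
        if "Id" in raw.columns:
            raw = raw.rename(columns={"Id": "participant"})
        else:
            raise DataError("covariate file needs a 'participant' (or 'Id') column")
    raw["participant"] = raw["participant"].astype(str)
    missing = [c for c in MODERATOR_COLUMNS if c not in raw.columns]
    if missing:
        warnings.warn(
            f"covariate columns missing ({', '.join(missing)}); "
            "interactions for those moderators are disabled",
            stacklevel=2,
        )
    return raw


# ---------------------------------------------------------------------------
# writers


def write_streams(streams: dict[str, ParticipantStream], steps_path, hr_path) -> None:
    """Write minute steps and per-minute HR samples in the reader dialects.

    Idle minutes (zero steps) are omitted from the steps file; the HR file
    carries one synthetic sample row per worn minute.
    """
    step_parts, hr_parts = [], []
    for pid in sorted(streams):
        s = streams[pid]
        ts = pd.date_range(pd.Timestamp(s.start), periods=s.steps.size, freq="min")
        nz = s.steps > 0
        step_parts.append(
            pd.DataFrame({"Id": pid, "ActivityMinute": ts[nz], "Steps": s.steps[nz]})
        )
        worn = s.hr_present
        hr_parts.append(pd.DataFrame({"Id": pid, "Time": ts[worn], "Value": 72}))
    pd.concat(step_parts, ignore_index=True).to_csv(steps_path, index=False)
    pd.concat(hr_parts, ignore_index=True).to_csv(hr_path, index=False)


def write_urges(urges: pd.DataFrame, path) -> None:
    out = urges.rename(
        columns={"participant": "Id", "timestamp": "Timestamp", "urge": "Urge", "prompted": "Prompted"}
    )
    out.to_csv(path, index=False)


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write a full synthetic cohort (CSV dialects + ground-truth JSON sidecar)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "steps": outdir / "minute_steps.csv",
        "heart_rate": outdir / "heart_rate.csv",
        "urges": outdir / "urges.csv",
        "covariates": outdir / "covariates.csv",
        "followup": outdir / "followup.csv",
        "truth": outdir / "ground_truth.json",
    }
    write_streams(cohort.streams, paths["steps"], paths["heart_rate"])
    write_urges(cohort.urges, paths["urges"])
    cohort.covariates.to_csv(paths["covariates"], index=False)
    cohort.followup.to_csv(paths["followup"], index=False)
    cohort.truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def streams_from_tables(
    steps: pd.DataFrame,
    heart_rate: pd.DataFrame,
    start: date | None = None,
    n_days: int | None = None,
) -> dict[str, ParticipantStream]:
    """Assemble dense per-participant streams from reader outputs.

    The grid for each participant spans ``start`` to ``start + n_days``;
    by default it covers that participant's observed date range. Absent
    minutes get zero steps and missing HR.
    """
    out: dict[str, ParticipantStream] = {}
    hr_by_pid = dict(tuple(heart_rate.groupby("participant"))) if len(heart_rate) else {}
    for pid, grp in steps.groupby("participant"):
        hr = hr_by_pid.pop(pid, None)
        ts_all = [grp["timestamp"]] + ([hr["timestamp"]] if hr is not None else [])
        lo = min(t.min() for t in ts_all)
        hi = max(t.max() for t in ts_all)
        p_start = start or lo.date()
        p_days = n_days or (hi.date() - p_start).days + 1
        size = p_days * MINUTES_PER_DAY
        arr_steps = np.zeros(size, dtype=np.int64)
        arr_hr = np.zeros(size, dtype=bool)
        origin = pd.Timestamp(p_start)
        idx = ((grp["timestamp"] - origin).dt.total_seconds() // 60).astype(int).to_numpy()
        ok = (idx >= 0) & (idx < size)
        arr_steps[idx[ok]] = grp["steps"].to_numpy()[ok]
        if hr is not None:
            hidx = ((hr["timestamp"] - origin).dt.total_seconds() // 60).astype(int).to_numpy()
            ok = (hidx >= 0) & (hidx < size)
            arr_hr[hidx[ok]] = True
        out[pid] = ParticipantStream(pid, p_start, arr_steps, arr_hr)
    # participants with HR but no steps
    for pid, hr in hr_by_pid.items():
        lo, hi = hr["timestamp"].min(), hr["timestamp"].max()
        p_start = start or lo.date()
        p_days = n_days or (hi.date() - p_start).days + 1
        size = p_days * MINUTES_PER_DAY
        arr_hr = np.zeros(size, dtype=bool)
        origin = pd.Timestamp(p_start)
        hidx = ((hr["timestamp"] - origin).dt.total_seconds() // 60).astype(int).to_numpy()
        ok = (hidx >= 0) & (hidx < size)
        arr_hr[hidx[ok]] = True
        out[pid] = ParticipantStream(pid, p_start, np.zeros(size, dtype=np.int64), arr_hr)
    return out
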