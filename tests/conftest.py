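import sys
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from stepurge import CohortConfig, ParticipantStream
from stepurge.streams import MINUTES_PER_DAY

DAY0 = date(2017, 1, 2)


def make_stream(
    pid: str = "P000",
    n_days: int = 1,
    steps_fn=None,
    hr_minutes=None,
    start: date = DAY0,
) -> ParticipantStream:
    """Hand-built dense stream: ``hr_minutes`` lists worn minute-of-day
    ranges (lo, hi) applied to every day; ``steps_fn(abs_minute)`` gives
    per-minute steps (default 0)."""
    n = n_days * MINUTES_PER_DAY
    steps = np.zeros(n, dtype=np.int64)
    if steps_fn is not None:
        steps = np.array([steps_fn(i) for i in range(n)], dtype=np.int64)
    hr = np.zeros(n, dtype=bool)
    if hr_minutes:
        mod = np.arange(n) % MINUTES_PER_DAY
        for lo, hi in hr_minutes:
            hr |= (mod >= lo) & (mod < hi)
    return ParticipantStream(pid, start, steps, hr)


def urges_frame(pid, minute_urges, start: date = DAY0) -> pd.DataFrame:
    """Urge events from (abs_minute, urge[, prompted]) tuples."""
    rows = []
    origin = pd.Timestamp(start)
    for tup in minute_urges:
        m, u = tup[0], tup[1]
        prompted = tup[2] if len(tup) > 2 else True
        rows.append(
            {"participant": pid, "timestamp": origin + pd.Timedelta(minutes=int(m)),
             "urge": int(u), "prompted": bool(prompted)}
        )
    return pd.DataFrame(rows)


@pytest.fixture
def small_config():
    """Quick cohort at reduced scale with the default (study-like) effects."""
    return CohortConfig(n_participants=10, study_days=25, seed=11)


@pytest.fixture
def null_config():
    """All effects and responders off: pure noise around the base urge."""
    return CohortConfig(
        n_participants=10, study_days=25, seed=7,
        day_beta=0.0, window_beta_30=0.0, responder_fraction=0.0,
    )
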