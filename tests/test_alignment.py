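"""Panel alignment: lookback accumulation, panels, midpoint, outliers."""

import warnings
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import DAY0, make_stream, urges_frame
from stepurge import (
    accumulate_window_steps,
    baseline_followup_change,
    build_day_panel,
    build_window_panel,
    flag_outliers,
    split_midpoint,
)
from stepurge.streams import MINUTES_PER_DAY


def test_lookback_sums_toy_grid_against_direct_summation():
    # steps: 10/min for the 30 minutes before the event, 4/min for the 30 before that
    def steps_fn(i):
        if 770 <= i < 800:
            return 10
        if 740 <= i < 770:
            return 4
        return 0

    stream = make_stream(steps_fn=steps_fn, hr_minutes=[(600, 1320)])
    event = pd.Timestamp(DAY0) + pd.Timedelta(minutes=800)
    assert accumulate_window_steps(stream, event, 30) == (300, 1.0)
    brute_60 = sum(steps_fn(i) for i in range(740, 800))
    assert accumulate_window_steps(stream, event, 60)[0] == brute_60 == 420
    # the event's own minute is excluded: steps at minute 800 must not count
    stream2 = make_stream(steps_fn=lambda i: 50 if i == 800 else steps_fn(i),
                          hr_minutes=[(600, 1320)])
    assert accumulate_window_steps(stream2, event, 30)[0] == 300


def test_lookback_zero_steps_and_partial_coverage():
    stream = make_stream(hr_minutes=[(785, 1320)])  # worn only from 13:05
    event = pd.Timestamp(DAY0) + pd.Timedelta(minutes=800)
    steps, cov = accumulate_window_steps(stream, event, 30)
    assert steps == 0
    assert cov == pytest.approx(15 / 30)


def test_event_before_stream_start_has_zero_coverage():
    stream = make_stream(hr_minutes=[(0, 1440)])
    early = pd.Timestamp(DAY0) - pd.Timedelta(minutes=5)
    assert accumulate_window_steps(stream, early, 30) == (0, 0.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_nested_windows_are_monotone(seed):
    rng = np.random.default_rng(seed)
    stream = make_stream(steps_fn=lambda i: int(rng.integers(0, 20)), hr_minutes=[(600, 1320)])
    event = pd.Timestamp(DAY0) + pd.Timedelta(minutes=int(rng.integers(600, 1320)))
    sums = [accumulate_window_steps(stream, event, w)[0] for w in (5, 30, 60, 120)]
    assert sums == sorted(sums)


def _day_records(rows):
    return pd.DataFrame(
        rows, columns=["participant", "date", "valid", "daily_steps", "mean_urge", "n_urges"]
    )


def test_day_panel_rows_and_traceability():
    d = [date(2017, 1, 2 + i) for i in range(3)]
    recs = _day_records(
        [
            ("A", d[0], True, 5000, 4.0, 3), ("A", d[1], True, 6000, 5.0, 2),
            ("A", d[2], True, 7000, np.nan, 0),  # no urges that day -> dropped
            ("B", d[0], True, 4000, 6.0, 1), ("B", d[1], True, 3000, 2.0, 4),
            ("B", d[2], False, 9000, 5.0, 2),  # invalid day -> dropped
        ]
    )
    panel = build_day_panel(recs)
    assert len(panel) == 4
    assert panel.loc[(panel.participant == "A") & (panel.date == d[1]), "daily_steps"].item() == 6000
    assert build_day_panel(recs[recs.valid == False]).empty  # noqa: E712


def test_day_panel_is_order_independent():
    d = [date(2017, 1, 2 + i) for i in range(4)]
    recs = _day_records(
        [("A", dd, True, 1000 * i, float(i + 1), 1) for i, dd in enumerate(d)]
        + [("B", dd, True, 500 * i, float(i + 2), 2) for i, dd in enumerate(d)]
    )
    shuffled = recs.sample(frac=1, random_state=3).reset_index(drop=True)
    pd.testing.assert_frame_equal(build_day_panel(recs), build_day_panel(shuffled))


def test_window_panel_coverage_flags_events_in_nonwear_gaps():
    # worn except 12:00-15:00; one event inside the gap, one in full wear
    stream = make_stream(hr_minutes=[(600, 720), (900, 1320)], steps_fn=lambda i: 1)
    urges = urges_frame("P000", [(860, 5), (1100, 4)])
    recs = pd.DataFrame(
        {"participant": ["P000"], "date": [DAY0], "valid": [True],
         "daily_steps": [1440], "mean_urge": [4.5], "n_urges": [2]}
    )
    panel = build_window_panel({"P000": stream}, urges, recs)
    assert len(panel) == 2  # both events kept in the panel ...
    in_gap = panel.iloc[0]
    assert in_gap["coverage_30"] == 0.0  # ... but the gap event fails every coverage test
    assert panel.iloc[1]["coverage_30"] == 1.0
    assert in_gap["steps_30"] == 30  # steps still summed from the minute grid


def test_window_panel_order_independent_and_nested():
    rng = np.random.default_rng(2)
    stream = make_stream(n_days=2, hr_minutes=[(600, 1320)],
                         steps_fn=lambda i: int(rng.integers(0, 30)))
    urges = urges_frame("P000", [(700, 3), (900, 7), (2000, 5), (700 + 1440, 2)])
    recs = pd.DataFrame(
        {"participant": "P000", "date": [DAY0, date(2017, 1, 3)], "valid": True,
         "daily_steps": 0, "mean_urge": 4.0, "n_urges": 2}
    )
    panel = build_window_panel({"P000": stream}, urges, recs)
    shuffled = build_window_panel({"P000": stream}, urges.sample(frac=1, random_state=1), recs)
    pd.testing.assert_frame_equal(panel, shuffled)
    for _, row in panel.iterrows():
        assert row["steps_5"] <= row["steps_30"] <= row["steps_60"] <= row["steps_120"]


def test_empty_cohort_yields_empty_panels():
    empty = pd.DataFrame(columns=["participant", "date", "valid", "daily_steps", "mean_urge", "n_urges"])
    assert build_day_panel(empty).empty
    urges = urges_frame("P000", [(700, 3)])
    assert build_window_panel({}, urges, empty).empty


def test_midpoint_split_even_count_matches_halves():
    d = [date(2017, 1, 2 + i) for i in range(4)]
    recs = pd.DataFrame(
        {"participant": "A", "date": d, "valid": True,
         "daily_steps": [1000, 1000, 1000, 1000], "mean_urge": [2.0, 2.0, 6.0, 6.0]}
    )
    m = split_midpoint(recs)
    assert m.pre_mean_urge == 2.0 and m.post_mean_urge == 6.0
    assert m.pre_mean_steps == m.post_mean_steps == 1000.0  # constant steps symmetry


def test_midpoint_only_counts_valid_days_and_needs_two():
    d = [date(2017, 1, 2 + i) for i in range(5)]
    recs = pd.DataFrame(
        {"participant": "A", "date": d, "valid": [True, False, True, True, False],
         "daily_steps": [100, 999999, 200, 300, 999999], "mean_urge": [1.0, 9.0, 5.0, 9.0, 9.0]}
    )
    m = split_midpoint(recs)  # valid days: 100/1.0, 200/5.0, 300/9.0 -> midpoint 2nd valid day
    assert m.pre_mean_urge == 1.0
    assert m.post_mean_urge == pytest.approx(7.0)
    single = recs.iloc[[0]]
    assert split_midpoint(single) is None


def test_midpoint_recovers_planted_step_increase():
    rng = np.random.default_rng(0)
    n = 40
    steps = np.concatenate([rng.normal(5000, 300, n // 2), rng.normal(7000, 300, n // 2)])
    recs = pd.DataFrame(
        {"participant": "A", "date": pd.date_range("2017-01-02", periods=n).date,
         "valid": True, "daily_steps": steps, "mean_urge": 5.0}
    )
    m = split_midpoint(recs)
    assert m.post_mean_steps - m.pre_mean_steps == pytest.approx(2000, abs=300)


def test_outlier_fences_hand_computed():
    mask = flag_outliers([1, 2, 3, 4, 100])
    # Q1=2, Q3=4 under linear interpolation -> upper fence 7: only 100 flagged
    assert list(mask) == [False, False, False, False, True]
    assert not flag_outliers([5, 5, 5, 5, 5]).any()  # zero IQR, no flags
    assert not flag_outliers([1, 2, 3, 4, 5, 6]).any()


def test_outliers_warns_below_four_values():
    with pytest.warns(UserWarning):
        mask = flag_outliers([1.0, 2.0])
    assert not mask.any()


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.integers(-10_000, 10_000), min_size=4, max_size=40),
    st.integers(1, 50), st.integers(-100, 100),
)
def test_outlier_mask_is_affine_invariant(values, a, b):
    # integer-valued inputs keep every quantile/fence computation exact in
    # binary floating point, so the invariance is not blurred by rounding
    base = flag_outliers([float(v) for v in values])
    scaled = flag_outliers([float(a * v + b) for v in values])
    assert list(base) == list(scaled)


def test_cigarette_change_toy_table():
    baseline = pd.DataFrame({"participant": ["A", "B", "C"], "cigs_per_day": [10, 20, 6]})
    followup = pd.DataFrame({"participant": ["A", "B", "C"], "cigs_per_day": [7, 14, 6]})
    changes, summary = baseline_followup_change(baseline, followup)
    assert list(changes["change"]) == [-3, -6, 0]
    assert summary["mean_change"] == pytest.approx(-3.0)
    assert summary["n_missing_followup"] == 0


def test_cigarette_change_attrition_and_errors():
    baseline = pd.DataFrame({"participant": ["A", "B"], "cigs_per_day": [10, 20]})
    followup = pd.DataFrame({"participant": ["A"], "cigs_per_day": [10]})
    changes, summary = baseline_followup_change(baseline, followup)
    assert list(changes["change"]) == [0]
    assert summary["n_missing_followup"] == 1
    with pytest.raises(ValueError):
        baseline_followup_change(baseline, pd.DataFrame({"participant": ["Z"], "cigs_per_day": [1]}))
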