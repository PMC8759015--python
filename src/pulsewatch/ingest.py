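"""Reading HR/sleep streams and sleep-aware day segmentation.

The watch stores sleep as *state changes* (awake / light / deep), so nightly
sleep intervals must be reconstructed from change points. A night is searched
in a noon-to-noon window and attributed to the study day on whose evening
sleep begins. The asleep period runs from the first non-awake state change to
the last state change of that window; asleep series shorter than 3 hours and
nights without any recorded sleep state are excluded from asleep analysis.
Awake samples of a day are those between the bounding nights; when a bounding
night is unrecorded the awake window falls back to a 9 AM - 9 PM clock window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HOUR = pd.Timedelta(hours=1)

SLEEP_STATES = ("awake", "light", "deep")
MIN_SLEEP_H = 3.0  # asleep series shorter than this are excluded
DEFAULT_AWAKE_START_H = 9  # 9 AM, used when the bounding night is unrecorded
DEFAULT_AWAKE_END_H = 21  # 9 PM


class ParseError(ValueError):
    """Malformed input row; the message names the offending line."""


@dataclass(frozen=True)
class SleepInterval:
    """One night, attributed to the study day on whose evening it starts."""

    subject_id: str
    night_day: int
    start: pd.Timestamp | None
    end: pd.Timestamp | None
    status: str  # "detected" | "excluded_short" | "missing"

    @property
    def duration_h(self) -> float:
        if self.start is None or self.end is None:
            return float("nan")
        return (self.end - self.start) / HOUR


@dataclass(frozen=True)
class DaySegments:
    """The HR samples of one subject-day split into asleep and awake."""

    subject_id: str
    study_day: int
    asleep_samples: np.ndarray | None  # None when the night is excluded/missing
    awake_samples: np.ndarray
    awake_window_source: str  # "sleep_bounds" | "default_window"


# -- readers ---------------------------------------------------------------


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    if df.empty and not set(required) <= set(df.columns):
        return pd.DataFrame(columns=list(required))
    missing = set(required) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if ts.isna().any():
        line = int(np.flatnonzero(ts.isna())[0]) + 2  # +1 header, +1 1-based
        raise ParseError(f"{path}: malformed ISO-8601 timestamp at line {line}")
    df["timestamp"] = ts
    df = df.sort_values(["subject_id", "timestamp"], kind="mergesort")
    df = df.drop_duplicates(["subject_id", "timestamp"], keep="last")
    return df.reset_index(drop=True)


def read_hr_stream(path: str | Path) -> pd.DataFrame:
    """Read hr.csv (subject_id, timestamp, hr_bpm), sorted and de-duplicated."""
    df = _read_csv(path, ["subject_id", "timestamp", "hr_bpm"])
    if df.empty:
        return df
    hr = pd.to_numeric(df["hr_bpm"], errors="coerce")
    if hr.isna().any():
        line = int(np.flatnonzero(hr.isna())[0]) + 2
        raise ParseError(f"{path}: non-numeric hr_bpm at line {line}")
    df["hr_bpm"] = hr.astype(float)
    return df


def read_sleep_events(path: str | Path) -> pd.DataFrame:
    """Read sleep.csv (subject_id, timestamp, state in awake/light/deep)."""
    df = _read_csv(path, ["subject_id", "timestamp", "state"])
    if df.empty:
        return df
    bad = ~df["state"].isin(SLEEP_STATES)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ParseError(
            f"{path}: unknown sleep state {df['state'].iloc[int(np.flatnonzero(bad)[0])]!r} "
            f"at line {line}"
        )
    return df


def read_allocation(path: str | Path) -> pd.DataFrame:
    """Read allocation.csv (subject_id, arm, anchor_date)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = {"subject_id", "arm", "anchor_date"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df["anchor_date"] = pd.to_datetime(df["anchor_date"]).dt.normalize()
    return df


# -- sleep interval reconstruction ----------------------------------------


def reconstruct_sleep_interval(
    events: pd.DataFrame, subject_id: str, night_day: int
) -> SleepInterval:
    """Reconstruct one night from the state changes in its noon-to-noon window.

    ``events`` must already be restricted to the window and chronological.
    The interval starts at the first non-awake state change and ends at the
    last state change in the window (normally the terminal transition back to
    awake). Degenerate inputs map to status "missing"; durations below 3 h
    map to "excluded_short".
    """
    if len(events) == 0:
        return SleepInterval(subject_id, night_day, None, None, "missing")
    non_awake = events[events["state"].isin(("light", "deep"))]
    if len(non_awake) == 0:
        return SleepInterval(subject_id, night_day, None, None, "missing")
    start = non_awake["timestamp"].iloc[0]
    end = events["timestamp"].iloc[-1]
    duration_h = (end - start) / HOUR
    status = "detected" if duration_h >= MIN_SLEEP_H else "excluded_short"
    return SleepInterval(subject_id, night_day, start, end, status)


def nightly_intervals(
    sleep: pd.DataFrame, allocation: pd.DataFrame, days: Iterable[int]
) -> list[SleepInterval]:
    """Reconstruct every subject's nights over ``days`` (study-day indices).

    The night of study day ``d`` is searched in [noon of d, noon of d+1),
    with calendar dates resolved through each subject's anchor_date.
    """
    days = list(days)
    anchors = pd.to_datetime(allocation.set_index("subject_id")["anchor_date"])
    out: list[SleepInterval] = []
    for sid, anchor in anchors.items():
        sub = sleep[sleep["subject_id"] == sid]
        for d in days:
            w0 = anchor + pd.Timedelta(days=d) + 12 * HOUR
            w1 = w0 + pd.Timedelta(days=1)
            win = sub[(sub["timestamp"] >= w0) & (sub["timestamp"] < w1)]
            out.append(reconstruct_sleep_interval(win, sid, d))
    return out


# -- day segmentation ------------------------------------------------------


def segment_day(
    hr: pd.DataFrame,
    interval: SleepInterval,
    prev_interval: SleepInterval | None,
    anchor: pd.Timestamp,
) -> DaySegments:
    """Split one subject-day's HR samples into asleep and awake sets.

    Asleep samples lie in the closed interval [start, end] of the day's
    attributed night (absent when that night is excluded or missing; a
    boundary sample counts as asleep). Awake samples lie strictly between the
    previous night's end and this night's start. Nights excluded for being
    short still bound the awake window; only their asleep series is dropped.
    When a bounding night is missing, the corresponding awake bound falls
    back to the 9 AM (inclusive) / 9 PM (exclusive) clock window of the day's
    calendar date and ``awake_window_source`` is "default_window".
    """
    d = interval.night_day
    daystart = anchor + pd.Timedelta(days=d)
    ts = hr["timestamp"]

    if interval.status == "detected":
        asleep_mask = (ts >= interval.start) & (ts <= interval.end)
        asleep = hr.loc[asleep_mask, "hr_bpm"].to_numpy()
    else:
        asleep = None

    source = "sleep_bounds"
    bounded = interval.status != "missing"
    prev_bounded = prev_interval is not None and prev_interval.status != "missing"
    if prev_bounded:
        lo, lo_incl = prev_interval.end, False
    else:
        lo, lo_incl = daystart + DEFAULT_AWAKE_START_H * HOUR, True
        source = "default_window"
    if bounded:
        hi = interval.start
    else:
        hi = daystart + DEFAULT_AWAKE_END_H * HOUR
        source = "default_window"
    awake_mask = ((ts > lo) | (lo_incl & (ts == lo))) & (ts < hi)
    awake = hr.loc[awake_mask, "hr_bpm"].to_numpy()
    return DaySegments(interval.subject_id, d, asleep, awake, source)


def segment_cohort(
    hr: pd.DataFrame,
    intervals: Sequence[SleepInterval],
    allocation: pd.DataFrame,
) -> list[DaySegments]:
    """Segment every subject-day covered by ``intervals``."""
    anchors = pd.to_datetime(allocation.set_index("subject_id")["anchor_date"])
    by_subj: dict[str, dict[int, SleepInterval]] = {}
    for iv in intervals:
        by_subj.setdefault(iv.subject_id, {})[iv.night_day] = iv
    out: list[DaySegments] = []
    for sid, nights in by_subj.items():
        sub = hr[hr["subject_id"] == sid]
        for d in sorted(nights):
            out.append(segment_day(sub, nights[d], nights.get(d - 1), anchors[sid]))
    return out


def sleep_duration_table(intervals: Sequence[SleepInterval]) -> pd.DataFrame:
    """One row (subject_id, study_day, duration_h) per *detected* night."""
    rows = [
        (iv.subject_id, iv.night_day, iv.duration_h)
        for iv in intervals
        if iv.status == "detected"
    ]
    return pd.DataFrame(rows, columns=["subject_id", "study_day", "duration_h"])


def night_accounting(intervals: Sequence[SleepInterval]) -> Mapping[str, int]:
    """Counts of nights by status, mirroring the exclusion bookkeeping."""
    out = {"detected": 0, "excluded_short": 0, "missing": 0}
    for iv in intervals:
        out[iv.status] += 1
    return out
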