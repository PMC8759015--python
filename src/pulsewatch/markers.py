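"""Percentile HR markers.

Each subject-day-period HR segment is summarized by three percentile markers:
low (2.5th), median (50th) and high (97.5th), yielding the six biomarkers
Awake-Low .. Asleep-High. Percentiles use linear interpolation between
closest ranks (index h = (n-1)p; the "type 7" rule of mainstream numeric
stacks).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ingest import DaySegments

MARKER_PERCENTILES = {"low": 0.025, "median": 0.5, "high": 0.975}


@dataclass(frozen=True)
class MarkerRecord:
    subject_id: str
    study_day: int
    period: str  # "awake" | "asleep"
    marker: str  # "low" | "median" | "high"
    value_bpm: float
    n_samples: int


def percentile(values: Sequence[float] | np.ndarray, p: float) -> float:
    """Linear-interpolation percentile of ``values`` at fraction ``p``.

    Exact at p=0 (minimum) and p=1 (maximum).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile of an empty segment is undefined")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a fraction in [0, 1]")
    return float(np.quantile(values, p, method="linear"))


def summarize_segment(
    subject_id: str, study_day: int, period: str, values: np.ndarray | None
) -> list[MarkerRecord]:
    """The three marker records of one segment; empty segments yield none."""
    if values is None or len(values) == 0:
        return []
    return [
        MarkerRecord(subject_id, study_day, period, m, percentile(values, p), len(values))
        for m, p in MARKER_PERCENTILES.items()
    ]


def build_marker_table(
    segments: Iterable[DaySegments], allocation: pd.DataFrame
) -> pd.DataFrame:
    """Long marker table keyed (subject, day, period, marker).

    Days with absent segments are simply missing rows (downstream models
    accept unbalanced data). Raises ``KeyError`` for a subject present in
    the segments but absent from the allocation table.
    """
    arms = allocation.set_index("subject_id")["arm"]
    records: list[MarkerRecord] = []
    for seg in segments:
        if seg.subject_id not in arms.index:
            raise KeyError(f"subject {seg.subject_id!r} missing from allocation table")
        records.extend(
            summarize_segment(seg.subject_id, seg.study_day, "asleep", seg.asleep_samples)
        )
        records.extend(
            summarize_segment(seg.subject_id, seg.study_day, "awake", seg.awake_samples)
        )
    df = pd.DataFrame(
        [
            (r.subject_id, r.study_day, arms[r.subject_id], r.period, r.marker, r.value_bpm, r.n_samples)
            for r in records
        ],
        columns=["subject_id", "study_day", "arm", "period", "marker", "value_bpm", "n_samples"],
    )
    return df
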