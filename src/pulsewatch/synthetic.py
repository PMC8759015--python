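"""Synthetic smartwatch cohort generator.

Produces HR sample streams, sleep state-change event streams, an allocation
table and a ground-truth record with known parameters, so that every
downstream stage (segmentation, percentile markers, mixed-model statistics)
can be tested against truth without any device data.

Two levels of generation are provided:

* :func:`simulate_cohort` — full raw streams (timestamped HR samples and
  sleep state-change events), which exercise the ingest/segmentation path.
* :func:`simulate_marker_table` — direct generation at the marker level from
  the random-intercept model the statistics consume, for fast replicate
  studies of ICC / contrast / effect-size recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import ConfigError, GeneratorConfig

HOUR = pd.Timedelta(hours=1)
MIN = pd.Timedelta(minutes=1)

#: inclusive physiological plausibility bounds applied to emitted samples
HR_CLIP_BPM = (25.0, 240.0)


@dataclass(frozen=True)
class SubjectState:
    """Per-subject ground truth shared by all of the subject's nights/days."""

    subject_id: str
    arm: str  # "placebo" | "active"
    intercept_bpm: float
    sleep_offset_h: float  # subject's habitual sleep duration offset
    anchor: pd.Timestamp  # calendar midnight of study day 0
    config: GeneratorConfig


@dataclass(frozen=True)
class TrueNight:
    """Ground-truth sleep interval of one night (attributed to study day)."""

    subject_id: str
    study_day: int
    start: pd.Timestamp
    end: pd.Timestamp
    recorded: bool  # False -> the watch stored no sleep states that night
    short: bool  # True -> truncated below the 3 h exclusion threshold

    @property
    def duration_h(self) -> float:
        return (self.end - self.start) / HOUR


def _day_midnight(state: SubjectState, day: int) -> pd.Timestamp:
    return state.anchor + pd.Timedelta(days=day)


def simulate_night(
    state: SubjectState, day: int, rng: np.random.Generator
) -> tuple[list[tuple[pd.Timestamp, str]], TrueNight]:
    """Simulate one night's sleep for ``state`` on the evening of ``day``.

    Returns the watch's state-change events (possibly empty when sleep states
    go unrecorded) and the true sleep interval. Events form a valid
    change-point stream: a first non-awake event at onset, alternating
    light/deep transitions, and a terminal awake event at sleep end.
    """
    cfg = state.config
    onset = (
        _day_midnight(state, day)
        + cfg.sleep_onset_hour * HOUR
        + rng.normal(0.0, cfg.sleep_onset_sd_min) * MIN
    )
    short = rng.random() < cfg.p_short_night
    missing = rng.random() < cfg.p_missing_sleep_states
    if short:
        duration_h = rng.uniform(1.0, 2.9)
    else:
        # the 3 h exclusion rule should only trip via p_short_night
        duration_h = max(
            rng.normal(
                cfg.sleep_duration_mean_h + state.sleep_offset_h, cfg.sleep_duration_sd_h
            ),
            3.05,
        )
    end = onset + duration_h * HOUR

    events: list[tuple[pd.Timestamp, str]] = []
    if not missing:
        events.append((onset, "light"))
        t, s = onset, "light"
        while True:
            t = t + max(rng.normal(90.0, 25.0), 20.0) * MIN
            if t >= end - 10 * MIN:
                break
            s = "deep" if s == "light" else "light"
            events.append((t, s))
        events.append((end, "awake"))
    night = TrueNight(state.subject_id, day, onset, end, recorded=not missing, short=short)
    return events, night


def _circadian(cfg: GeneratorConfig, ts: pd.Timestamp) -> float:
    h = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    return cfg.circadian_amp_bpm * np.cos(2 * np.pi * (h - cfg.circadian_phase_h) / 24.0)


def _effect(cfg: GeneratorConfig, arm: str, day: int, period: str) -> float:
    if arm != "active":
        return 0.0
    return float(cfg.effect_profile_bpm.get((day, period), 0.0))


def simulate_hr_stream(
    state: SubjectState,
    day: int,
    night: TrueNight,
    rng: np.random.Generator,
    cell_eps: Mapping[Tuple[int, str], float],
) -> list[tuple[pd.Timestamp, float]]:
    """HR samples over the noon-to-noon window of study day ``day``.

    The window runs from noon of ``day`` to noon of ``day + 1`` so that it
    contains the whole night attributed to ``day``. Samples are drawn on a
    ``base_sampling_min`` grid with a random phase; during daytime activity
    bursts the cadence tightens to ``burst_sampling_min`` and HR is elevated
    by ``burst_elevation_bpm`` (exercise). Awake samples after the night's
    end (the following morning) belong to study day ``day + 1``.

    ``cell_eps`` maps (study_day, period) to the subject's day-level
    within-subject deviation shared by all samples of that cell.
    """
    cfg = state.config
    t0 = _day_midnight(state, day) + 12 * HOUR
    t1 = t0 + 24 * HOUR

    phase = rng.uniform(0.0, cfg.base_sampling_min)
    base = np.arange(phase, 24 * 60.0, cfg.base_sampling_min)  # minutes past t0
    times = [t0 + m * MIN for m in base]

    # daytime activity bursts in the afternoon/evening awake stretch
    burst_windows: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    awake_evening_h = max((night.start - t0) / HOUR - 1.0, 0.0)
    for _ in range(cfg.activity_bursts_per_day):
        if awake_evening_h * 60.0 <= cfg.burst_len_min + 60.0:
            break
        start_min = rng.uniform(30.0, awake_evening_h * 60.0 - cfg.burst_len_min)
        b0 = t0 + start_min * MIN
        b1 = b0 + cfg.burst_len_min * MIN
        burst_windows.append((b0, b1))
        times = [t for t in times if not (b0 <= t < b1)]
        times.extend(b0 + m * MIN for m in np.arange(0.0, cfg.burst_len_min, cfg.burst_sampling_min))
    times.sort()

    samples: list[tuple[pd.Timestamp, float]] = []
    for ts in times:
        if not (t0 <= ts < t1):
            continue
        asleep = night.start <= ts <= night.end
        if asleep:
            period, eff_day = "asleep", day
            mu = cfg.mu_asleep_bpm
        else:
            period = "awake"
            eff_day = day if ts <= night.end else day + 1
            mu = cfg.mu_awake_bpm
        v = (
            mu
            + state.intercept_bpm
            + cell_eps.get((eff_day, period), 0.0)
            + _circadian(cfg, ts)
            + _effect(cfg, state.arm, eff_day, period)
            + rng.normal(0.0, cfg.sigma_sample_bpm)
        )
        if not asleep and any(b0 <= ts < b1 for b0, b1 in burst_windows):
            v += cfg.burst_elevation_bpm + rng.normal(0.0, 0.25 * cfg.sigma_sample_bpm)
        samples.append((ts, float(np.clip(v, *HR_CLIP_BPM))))
    return samples


def simulate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Simulate the full cohort; deterministic given ``config.seed``.

    Returns ``(hr, sleep, allocation, truth)``:

    * ``hr`` — columns subject_id, timestamp, hr_bpm (sorted per subject);
    * ``sleep`` — columns subject_id, timestamp, state (change points only);
    * ``allocation`` — columns subject_id, arm, anchor_date;
    * ``truth`` — dict with ``subjects`` (random intercepts), ``cells``
      (per subject-day-period true marker-level mean) and ``nights``
      (true sleep intervals with recorded/short flags) DataFrames.

    A lead-in night on the evening before the first study day is simulated so
    the first day's awake period has a proper morning boundary.
    """
    cfg = config
    if cfg.n_subjects < 1:
        raise ConfigError("empty cohort")
    anchor = pd.Timestamp(cfg.anchor_date)
    first, last = cfg.study_days
    arms = ["placebo"] * cfg.n_placebo + ["active"] * (cfg.n_subjects - cfg.n_placebo)

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    hr_rows, sleep_rows, cell_rows, night_rows, subj_rows = [], [], [], [], []
    for i, (arm, ss) in enumerate(zip(arms, seeds)):
        rng = np.random.default_rng(ss)
        sid = f"S{i + 1:02d}"
        b_i = rng.normal(0.0, cfg.sigma_b_bpm)
        sleep_off = rng.normal(0.0, cfg.sleep_duration_subject_sd_h)
        state = SubjectState(sid, arm, b_i, sleep_off, anchor, cfg)
        subj_rows.append((sid, arm, b_i))

        cell_eps: dict[tuple[int, str], float] = {}
        for d in range(first - 1, last + 2):
            for period in ("awake", "asleep"):
                cell_eps[(d, period)] = rng.normal(0.0, cfg.sigma_w_bpm)
        for d in cfg.days:
            for period in ("awake", "asleep"):
                mu = cfg.mu_awake_bpm if period == "awake" else cfg.mu_asleep_bpm
                cell_rows.append(
                    (
                        sid,
                        d,
                        period,
                        mu + b_i + cell_eps[(d, period)] + _effect(cfg, arm, d, period),
                        b_i,
                    )
                )

        for d in range(first - 1, last + 1):  # lead-in night + study nights
            events, night = simulate_night(state, d, rng)
            sleep_rows.extend((sid, ts, s) for ts, s in events)
            if d >= first:
                night_rows.append(
                    (sid, d, night.start, night.end, night.duration_h, night.recorded, night.short)
                )
            hr_rows.extend(
                (sid, ts, v) for ts, v in simulate_hr_stream(state, d, night, rng, cell_eps)
            )

    hr = pd.DataFrame(hr_rows, columns=["subject_id", "timestamp", "hr_bpm"])
    sleep = pd.DataFrame(sleep_rows, columns=["subject_id", "timestamp", "state"])
    for df in (hr, sleep):
        df.sort_values(["subject_id", "timestamp"], inplace=True, kind="mergesort")
        df.reset_index(drop=True, inplace=True)
    allocation = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:02d}" for i in range(cfg.n_subjects)],
            "arm": arms,
            "anchor_date": anchor.date().isoformat(),
        }
    )
    truth = {
        "subjects": pd.DataFrame(subj_rows, columns=["subject_id", "arm", "intercept_bpm"]),
        "cells": pd.DataFrame(
            cell_rows, columns=["subject_id", "study_day", "period", "true_mean_bpm", "intercept_bpm"]
        ),
        "nights": pd.DataFrame(
            night_rows,
            columns=["subject_id", "study_day", "start", "end", "duration_h", "recorded", "short"],
        ),
    }
    return hr, sleep, allocation, truth


def simulate_marker_table(
    n_subjects: int,
    days: Iterable[int],
    sigma_b: float,
    sigma_w: float,
    seed: int | np.random.SeedSequence,
    mu: float = 0.0,
    fixed_effects: Mapping[Tuple[int, str], float] | None = None,
    arms: Sequence[str] | None = None,
    allocation_ratio: Tuple[int, int] = (1, 2),
    drop: Iterable[Tuple[str, int]] = (),
    value_col: str = "value_bpm",
) -> pd.DataFrame:
    """Generate one marker's long table directly from the analysis model.

    ``value(i, d) = mu + fixed_effects[(d, arm_i)] + b_i + eps_id`` with
    ``b_i ~ N(0, sigma_b^2)`` and ``eps_id ~ N(0, sigma_w^2)``. Balanced over
    ``days`` unless (subject_id, day) pairs are listed in ``drop``.

    ``arms`` assigns one arm label per subject; by default subjects are split
    placebo:active by ``allocation_ratio`` (the trial's 1:2).
    """
    if sigma_b < 0 or sigma_w < 0:
        raise ConfigError("standard deviations must be >= 0")
    if n_subjects < 1:
        raise ConfigError("empty cohort")
    days = list(days)
    if arms is None:
        p, a = allocation_ratio
        n_pl = int(round(n_subjects * p / (p + a)))
        arms = ["placebo"] * n_pl + ["active"] * (n_subjects - n_pl)
    if len(arms) != n_subjects:
        raise ConfigError("arms must have one label per subject")
    fixed = dict(fixed_effects or {})
    dropset = set(drop)

    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sigma_b, n_subjects)
    rows = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        for d in days:
            eps = rng.normal(0.0, sigma_w)
            if (sid, d) in dropset:
                continue
            rows.append((sid, d, arms[i], mu + fixed.get((d, arms[i]), 0.0) + b[i] + eps))
    return pd.DataFrame(rows, columns=["subject_id", "study_day", "arm", value_col])


# -- writers ---------------------------------------------------------------


def write_cohort(
    outdir: str | Path,
    hr: pd.DataFrame,
    sleep: pd.DataFrame,
    allocation: pd.DataFrame,
    truth: dict | None = None,
) -> dict[str, Path]:
    """Write the generator output as the CSV formats the ingest module reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    hr = hr.assign(timestamp=hr["timestamp"].map(lambda t: t.isoformat()))
    sleep = sleep.assign(timestamp=sleep["timestamp"].map(lambda t: t.isoformat()))
    for name, df in [("hr", hr), ("sleep", sleep), ("allocation", allocation)]:
        paths[name] = out / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    if truth is not None:
        paths["truth"] = out / "truth.csv"
        truth["cells"].rename(
            columns={"true_mean_bpm": "true_mean", "intercept_bpm": "intercept"}
        ).to_csv(paths["truth"], index=False)
        paths["truth_nights"] = out / "truth_nights.csv"
        truth["nights"].to_csv(paths["truth_nights"], index=False)
    return paths
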