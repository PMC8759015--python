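"""Stream parsing, night reconstruction and day segmentation."""

import numpy as np
import pandas as pd
import pytest

from pulsewatch.ingest import (
    ParseError,
    SleepInterval,
    nightly_intervals,
    read_hr_stream,
    read_sleep_events,
    reconstruct_sleep_interval,
    segment_cohort,
    segment_day,
    sleep_duration_table,
)

T = pd.Timestamp
ANCHOR = T("2021-03-01")


def _events(*pairs):
    return pd.DataFrame(
        [(T(ts), state) for ts, state in pairs], columns=["timestamp", "state"]
    ).assign(subject_id="S01")[["subject_id", "timestamp", "state"]]


class TestReaders:
    def test_roundtrip_sorted_and_deduplicated(self, tmp_path):
        p = tmp_path / "hr.csv"
        p.write_text(
            "subject_id,timestamp,hr_bpm\n"
            "S01,2021-03-01T10:20:00,80\n"
            "S01,2021-03-01T10:00:00,70\n"
            "S01,2021-03-01T10:00:00,72\n"
            "S01,2021-03-01T10:10:00,75\n"
        )
        df = read_hr_stream(p)
        assert df["hr_bpm"].tolist() == [72.0, 75.0, 80.0]  # sorted, last dup kept
        assert df["timestamp"].is_monotonic_increasing

    def test_unknown_sleep_state_names_line(self, tmp_path):
        p = tmp_path / "sleep.csv"
        p.write_text(
            "subject_id,timestamp,state\n"
            "S01,2021-03-01T23:00:00,light\n"
            "S01,2021-03-02T01:00:00,rem\n"
        )
        with pytest.raises(ParseError, match="line 3"):
            read_sleep_events(p)

    def test_malformed_timestamp_names_line(self, tmp_path):
        p = tmp_path / "hr.csv"
        p.write_text("subject_id,timestamp,hr_bpm\nS01,yesterday,70\n")
        with pytest.raises(ParseError, match="line 2"):
            read_hr_stream(p)

    def test_empty_file_gives_empty_stream(self, tmp_path):
        p = tmp_path / "hr.csv"
        p.write_text("subject_id,timestamp,hr_bpm\n")
        assert len(read_hr_stream(p)) == 0

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_hr_stream(tmp_path / "absent.csv")


class TestReconstructSleepInterval:
    def test_hand_traced_normal_night(self):
        ev = _events(
            ("2021-03-01 23:40", "light"),
            ("2021-03-02 02:10", "deep"),
            ("2021-03-02 03:00", "light"),
            ("2021-03-02 06:50", "awake"),
        )
        iv = reconstruct_sleep_interval(ev, "S01", 0)
        assert iv.start == T("2021-03-01 23:40") and iv.end == T("2021-03-02 06:50")
        assert iv.duration_h == pytest.approx(7 + 10 / 60, abs=1e-9)
        assert iv.status == "detected"

    def test_short_night_excluded(self):
        ev = _events(("2021-03-02 01:00", "light"), ("2021-03-02 03:30", "awake"))
        iv = reconstruct_sleep_interval(ev, "S01", 0)
        assert iv.duration_h == pytest.approx(2.5) and iv.status == "excluded_short"

    def test_no_events_is_missing(self):
        iv = reconstruct_sleep_interval(_events(), "S01", 0)
        assert iv.status == "missing"

    def test_only_awake_events_is_missing(self):
        iv = reconstruct_sleep_interval(_events(("2021-03-01 13:00", "awake")), "S01", 0)
        assert iv.status == "missing"

    def test_leading_awake_ignored_for_start(self):
        ev = _events(
            ("2021-03-01 22:00", "awake"),
            ("2021-03-01 23:40", "light"),
            ("2021-03-02 06:50", "awake"),
        )
        iv = reconstruct_sleep_interval(ev, "S01", 0)
        assert iv.start == T("2021-03-01 23:40") and iv.status == "detected"

    def test_removing_internal_awake_events_never_lengthens(self):
        # Monotone robustness: drop non-terminal awake change points
        rng = np.random.default_rng(0)
        for _ in range(50):
            base = T("2021-03-01 22:00")
            times = sorted(rng.uniform(0, 12 * 60, size=rng.integers(3, 9)))
            states = [rng.choice(["light", "deep", "awake"]) for _ in times]
            ev = _events(*[(base + pd.Timedelta(minutes=m), s) for m, s in zip(times, states)])
            full = reconstruct_sleep_interval(ev, "S01", 0)
            keep = [i for i in range(len(ev)) if ev["state"].iloc[i] != "awake" or i == len(ev) - 1]
            pruned = reconstruct_sleep_interval(ev.iloc[keep], "S01", 0)
            if full.status == "missing":
                continue
            assert pruned.start == full.start
            assert pruned.duration_h <= full.duration_h + 1e-12


def _hr(times):
    return pd.DataFrame(
        {"subject_id": "S01", "timestamp": times, "hr_bpm": np.arange(len(times), dtype=float) + 60}
    )


class TestSegmentDay:
    def mk_interval(self, day, start, end, status="detected"):
        return SleepInterval("S01", day, None if start is None else T(start),
                             None if end is None else T(end), status)

    def test_awake_strictly_between_bounding_nights(self):
        prev = self.mk_interval(-1, "2021-02-28 23:00", "2021-03-01 06:00")
        cur = self.mk_interval(0, "2021-03-01 23:00", "2021-03-02 06:30")
        times = [T("2021-03-01 06:00"), T("2021-03-01 08:00"), T("2021-03-01 22:59"),
                 T("2021-03-01 23:00"), T("2021-03-02 01:00")]
        seg = segment_day(_hr(times), cur, prev, ANCHOR)
        # 06:00 belongs to the previous asleep interval, 23:00 to this one
        assert len(seg.awake_samples) == 2
        assert len(seg.asleep_samples) == 2
        assert seg.awake_window_source == "sleep_bounds"

    def test_missing_night_uses_default_clock_window(self):
        cur = self.mk_interval(0, None, None, "missing")
        times = [T("2021-03-01 08:59"), T("2021-03-01 09:00"), T("2021-03-01 20:59"),
                 T("2021-03-01 21:00")]
        seg = segment_day(_hr(times), cur, None, ANCHOR)
        assert seg.asleep_samples is None
        assert len(seg.awake_samples) == 2  # [9 AM, 9 PM)
        assert seg.awake_window_source == "default_window"

    def test_short_night_drops_asleep_but_keeps_boundaries(self):
        prev = self.mk_interval(-1, "2021-02-28 23:00", "2021-03-01 06:00")
        cur = self.mk_interval(0, "2021-03-01 23:00", "2021-03-02 01:00", "excluded_short")
        times = [T("2021-03-01 10:00"), T("2021-03-01 23:30")]
        seg = segment_day(_hr(times), cur, prev, ANCHOR)
        assert seg.asleep_samples is None
        assert len(seg.awake_samples) == 1  # 23:30 is inside the (dropped) night
        assert seg.awake_window_source == "sleep_bounds"

    def test_no_samples_in_window_is_empty_not_error(self):
        cur = self.mk_interval(0, "2021-03-01 23:00", "2021-03-02 06:00")
        seg = segment_day(_hr([T("2021-03-05 10:00")]), cur, None, ANCHOR)
        assert len(seg.awake_samples) == 0


class TestCohortProperties:
    def random_cohort(self, seed):
        """Toy stream with known night truth for brute-force comparison."""
        rng = np.random.default_rng(seed)
        nights = {}
        sleep_rows, hr_rows = [], []
        for d in range(-2, 2):
            onset = ANCHOR + pd.Timedelta(days=d, hours=22.0 + rng.uniform(0, 3))
            end = onset + pd.Timedelta(hours=rng.uniform(3.5, 9))
            nights[d] = (onset, end)
            sleep_rows += [("S01", onset, "light"), ("S01", end, "awake")]
        t = ANCHOR + pd.Timedelta(days=-2, hours=12)
        stop = ANCHOR + pd.Timedelta(days=2, hours=12)
        while t < stop:
            hr_rows.append(("S01", t, 60.0 + rng.normal()))
            t += pd.Timedelta(minutes=float(rng.uniform(5, 25)))
        sleep = pd.DataFrame(sleep_rows, columns=["subject_id", "timestamp", "state"])
        hr = pd.DataFrame(hr_rows, columns=["subject_id", "timestamp", "hr_bpm"])
        alloc = pd.DataFrame(
            {"subject_id": ["S01"], "arm": ["active"], "anchor_date": [ANCHOR]}
        )
        return hr, sleep, alloc, nights

    def test_partition_matches_brute_force_classifier(self):
        for seed in range(100):
            hr, sleep, alloc, nights = self.random_cohort(seed)
            ivs = nightly_intervals(sleep, alloc, range(-2, 2))
            segs = {s.study_day: s for s in segment_cohort(hr, ivs, alloc)}
            for d in range(-1, 2):  # days with detected bounding nights
                prev_end, start = nights[d - 1][1], nights[d][0]
                span = hr[(hr["timestamp"] > prev_end) & (hr["timestamp"] < nights[d][1])]
                # brute force: each sample in the day span is awake before the
                # night's start, asleep from start to end
                expect_awake = span.loc[span["timestamp"] < start, "hr_bpm"]
                expect_asleep = span.loc[span["timestamp"] >= start, "hr_bpm"]
                assert sorted(segs[d].awake_samples) == sorted(expect_awake)
                assert sorted(segs[d].asleep_samples) == sorted(expect_asleep)
                overlap = set(np.round(segs[d].awake_samples, 9)) & set(
                    np.round(segs[d].asleep_samples, 9)
                )
                assert not overlap

    def test_day_attribution_shifts_with_whole_day_shift(self):
        hr, sleep, alloc, _ = self.random_cohort(7)
        ivs = nightly_intervals(sleep, alloc, range(-2, 2))
        shift = pd.Timedelta(days=3)
        sleep2 = sleep.assign(timestamp=sleep["timestamp"] + shift)
        ivs2 = nightly_intervals(sleep2, alloc, range(1, 5))
        for a, b in zip(ivs, ivs2):
            assert b.night_day == a.night_day + 3
            assert b.start == a.start + shift and b.end == a.end + shift
            assert b.status == a.status


class TestSleepDurationTable:
    def test_counts_and_exclusions(self, default_cohort):
        cfg, hr, sleep, alloc, truth = default_cohort
        ivs = nightly_intervals(sleep, alloc, cfg.days)
        tab = sleep_duration_table(ivs)
        n_detected = sum(1 for iv in ivs if iv.status == "detected")
        assert len(tab) == n_detected
        assert (tab["duration_h"] >= 3.0).all()
        # truth: recorded, non-short nights are exactly the detected ones
        expect = truth["nights"].query("recorded and not short")
        assert len(tab) == len(expect)

    def test_all_missing_gives_empty_table(self):
        ivs = [SleepInterval("S01", d, None, None, "missing") for d in range(5)]
        assert len(sleep_duration_table(ivs)) == 0
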