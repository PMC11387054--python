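"""Cleaning rules, thermal exclusion and stream alignment."""

import numpy as np
import pandas as pd
import pytest

from wakeflight.preprocessing import (
    AlignmentError,
    BirdTrajectory,
    CleaningConfig,
    ParseError,
    StreamOffsetError,
    align_streams,
    clean_trajectory,
    detect_thermalling,
    load_accel,
    load_hr,
    load_tracks,
    _bin_mean,
)
from wakeflight.simulate import circling_track, write_fixture


def _straight_track(n=600, rate=5.0, speed=12.0, bird=0):
    t = np.arange(n) / rate
    df = pd.DataFrame({
        "t": t, "east": np.zeros(n), "north": speed * t,
        "up": np.full(n, 100.0), "accuracy": np.ones(n, int),
    })
    return BirdTrajectory.from_frame(df, bird)


class TestLoaders:
    def test_fixture_parses(self, small_flock, tmp_path):
        write_fixture(small_flock, tmp_path)
        tracks = load_tracks(sorted(tmp_path.glob("track_*.csv")))
        assert [tr.bird_id for tr in tracks] == sorted(small_flock.tracks)
        assert load_accel(sorted(tmp_path.glob("accel_*.csv")))
        assert load_hr(sorted(tmp_path.glob("hr_*.csv")))

    def test_track_duration_from_row_count(self, small_flock, tmp_path):
        write_fixture(small_flock, tmp_path)
        tr = load_tracks([tmp_path / "track_000.csv"])[0]
        assert tr.duration_s == pytest.approx(60.0)
        assert tr.rate_hz == pytest.approx(5.0)

    def test_shuffled_rows_error_names_first_offender(self, tmp_path):
        df = pd.DataFrame({
            "t": [0.0, 0.4, 0.2, 0.6], "east": 0.0, "north": 0.0,
            "up": 100.0, "accuracy": 1,
        })
        p = tmp_path / "track_007.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ParseError, match=r"line 4.*t=0\.2"):
            load_tracks([p])

    def test_missing_column_error(self, tmp_path):
        p = tmp_path / "accel_001.csv"
        pd.DataFrame({"t": [0.0], "ax": [0.0], "ay": [0.0]}).to_csv(p, index=False)
        with pytest.raises(ParseError, match="missing columns"):
            load_accel([p])


class TestCleaning:
    def test_full_trim_warns_not_fails(self):
        tr = _straight_track(n=6000)  # 20 min
        with pytest.warns(UserWarning, match="trimming"):
            out = clean_trajectory(tr, CleaningConfig(trim_s=600.0))
        assert out.duration_s < 2.0 or len(out.t) == 0

    def test_single_masked_sample_interpolated(self):
        tr = _straight_track(n=100)
        tr.accuracy_ok[50] = False
        tr.valid[50] = False
        out = clean_trajectory(tr, CleaningConfig(trim_s=0.0))
        assert out.valid[50]
        # linear interpolation between the neighbours
        expect = 0.5 * (out.position[49, 1] + out.position[51, 1])
        assert out.position[50, 1] == pytest.approx(expect)

    def test_two_second_gap_stays_masked(self):
        tr = _straight_track(n=100)
        tr.valid[40:50] = False  # 10 samples = 2.0 s
        tr.accuracy_ok[40:50] = False
        out = clean_trajectory(tr, CleaningConfig(trim_s=0.0))
        assert not out.valid[40:50].any()

    def test_cleaning_is_idempotent(self, flock600):
        cfg = CleaningConfig(trim_s=30.0)
        tr = BirdTrajectory.from_frame(flock600.tracks[1], 1)
        once = clean_trajectory(tr, cfg)
        twice = clean_trajectory(once, cfg)
        np.testing.assert_array_equal(once.t, twice.t)
        np.testing.assert_array_equal(once.valid, twice.valid)
        np.testing.assert_allclose(once.position, twice.position)

    def test_interpolation_stays_inside_neighbour_hull(self):
        rng = np.random.default_rng(1)
        tr = _straight_track(n=200)
        tr.position[:, 0] += rng.normal(0, 0.5, 200)
        gap = slice(90, 93)
        tr.valid[gap] = False
        tr.accuracy_ok[gap] = False
        out = clean_trajectory(tr, CleaningConfig(trim_s=0.0))
        for j in range(3):
            lo = min(out.position[89, j], out.position[93, j])
            hi = max(out.position[89, j], out.position[93, j])
            assert (out.position[gap, j] >= lo - 1e-9).all()
            assert (out.position[gap, j] <= hi + 1e-9).all()


class TestThermalDetection:
    def test_straight_flight_empty_mask(self):
        tr = _straight_track()
        assert not detect_thermalling(tr).any()

    def test_circling_climb_flagged(self):
        df = circling_track(radius_m=15.0, climb_ms=1.0, duration_s=60.0, lead_in_s=30.0)
        tr = BirdTrajectory.from_frame(df, 0)
        mask = detect_thermalling(tr)
        circ = np.arange(len(df)) >= 30 * 5
        coverage = mask[circ].mean()
        assert coverage >= 0.9
        assert mask[: 20 * 5].mean() < 0.5  # lead-in mostly untouched

    def test_mixed_flight_fraction_in_study_range(self):
        """On a flight with a single short thermal the masked fraction
        stays inside the study's reported 0-30% range."""
        df = circling_track(radius_m=15.0, climb_ms=1.0, duration_s=40.0, lead_in_s=260.0)
        tr = BirdTrajectory.from_frame(df, 0)
        frac = detect_thermalling(tr).mean()
        assert 0.0 <= frac <= 0.30


class TestAlignment:
    def test_bin_mean_arithmetic(self):
        out = _bin_mean(np.array([1.0, 2.0, 3.0, 4.0]), np.zeros(4, int), 1)
        assert out[0] == pytest.approx(2.5)

    def test_constant_vedba_preserved(self):
        """A constant 20 Hz VeDBA aggregates to the same constant at 5 Hz."""
        n5, rate = 300, 5.0
        t5 = np.arange(n5) / rate
        df = pd.DataFrame({"t": t5, "east": 0.0, "north": 12.0 * t5,
                           "up": 100.0, "accuracy": 1})
        tr = BirdTrajectory.from_frame(df, 0)
        t20 = np.arange(n5 * 4) / 20.0
        # alternating +/-1 g on one axis: dynamic component is +/-1
        accel = pd.DataFrame({
            "t": t20, "ax": np.where(np.arange(len(t20)) % 2 == 0, 1.0, -1.0),
            "ay": 0.0, "az": 1.0,
        })
        al = align_streams(tr, accel, cfg=CleaningConfig(trim_s=0.0))
        mid = al.table["vedba"].to_numpy()[20:-20]
        assert np.nanstd(mid) < 1e-6
        assert np.nanmean(mid) == pytest.approx(1.0, rel=1e-6)

    def test_alignment_conserves_mean_vedba(self, flock600):
        from wakeflight import signals

        tr = BirdTrajectory.from_frame(flock600.tracks[1], 1)
        tr = clean_trajectory(tr, CleaningConfig(trim_s=0.0))
        al = align_streams(tr, flock600.accel[1], cfg=CleaningConfig(trim_s=0.0))
        v20 = signals.vedba(flock600.accel[1][["ax", "ay", "az"]].to_numpy(), 20.0, 4.0)
        assert np.nanmean(al.table["vedba"]) == pytest.approx(np.nanmean(v20), rel=1e-3)

    def test_injected_offset_excludes_bird(self, flock600):
        tr = clean_trajectory(
            BirdTrajectory.from_frame(flock600.tracks[1], 1), CleaningConfig(trim_s=0.0)
        )
        accel = flock600.accel[1].copy()
        accel["t"] += 1.5
        with pytest.raises(StreamOffsetError):
            align_streams(tr, accel, cfg=CleaningConfig(trim_s=0.0))

    def test_clean_streams_not_excluded(self, flock600):
        for b in range(3):
            tr = clean_trajectory(
                BirdTrajectory.from_frame(flock600.tracks[b], b), CleaningConfig(trim_s=0.0)
            )
            al = align_streams(tr, flock600.accel[b], flock600.hr.get(b),
                               cfg=CleaningConfig(trim_s=0.0))
            assert abs(al.stream_offset_s) <= 0.6

    def test_disjoint_time_support_raises(self):
        tr = _straight_track(n=100)
        accel = pd.DataFrame({"t": np.arange(100) / 20.0 + 1000.0,
                              "ax": 0.0, "ay": 0.0, "az": 1.0})
        with pytest.raises(AlignmentError):
            align_streams(tr, accel, cfg=CleaningConfig(trim_s=0.0))
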