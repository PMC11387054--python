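"""Bout extraction, gap bridging, glide exclusion and summaries."""

import numpy as np
import pandas as pd
import pytest

from wakeflight.bouts import (
    Bout,
    BoutConfig,
    apply_glide_exclusion,
    bouts_to_frame,
    extract_bouts,
    summarize_bouts,
)
from wakeflight.preprocessing import AlignedStreams

RATE = 5.0


def _states(layout):
    """Build a state table from a list of (n_samples, in_wake, leader, valid)."""
    rows = []
    for n, inw, lead, valid in layout:
        rows += [(inw, lead, valid)] * n
    t = np.arange(len(rows)) / RATE
    if not rows:
        return pd.DataFrame({"t": t, "in_wake": [], "leader": [], "valid": []})
    inw, lead, valid = zip(*rows)
    return pd.DataFrame({
        "t": t, "in_wake": inw, "leader": lead, "valid": valid,
    })


class TestExtraction:
    def test_sub_second_gap_bridged(self):
        st = _states([(10, True, 3, True), (3, True, 3, False), (10, True, 3, True)])
        bouts = extract_bouts(st, BoutConfig())
        assert len(bouts) == 1
        assert bouts[0].duration_s == pytest.approx(4.6)  # 23 samples x 0.2 s
        assert bouts[0].leader_id == 3

    def test_gap_with_different_leader_not_bridged(self):
        st = _states([(10, True, 3, True), (3, True, 3, False), (10, True, 4, True)])
        bouts = extract_bouts(st, BoutConfig())
        assert [b.leader_id for b in bouts] == [3, 4]

    def test_leader_change_splits_bout(self):
        st = _states([(10, True, 1, True), (10, True, 2, True)])
        bouts = extract_bouts(st, BoutConfig())
        assert len(bouts) == 2
        assert [b.leader_id for b in bouts] == [1, 2]

    def test_short_run_dropped(self):
        st = _states([(8, False, -1, True)])  # 1.6 s < 2 s minimum
        assert extract_bouts(st, BoutConfig()) == []

    def test_state_flip_splits_even_when_brief(self):
        # a 0.4 s excursion to the other state splits; bridging is for
        # missing data only
        st = _states([(15, True, 1, True), (2, False, -1, True), (15, True, 1, True)])
        bouts = extract_bouts(st, BoutConfig())
        assert len(bouts) == 2
        assert all(b.in_wake for b in bouts)

    def test_empty_input(self):
        assert extract_bouts(_states([]), BoutConfig()) == []

    def test_min_duration_monotonicity(self):
        rng = np.random.default_rng(6)
        layout = [(int(rng.integers(3, 30)), bool(rng.random() < 0.5),
                  int(rng.integers(0, 3)), True) for _ in range(50)]
        st = _states(layout)
        counts = [len(extract_bouts(st, BoutConfig(min_duration_s=m)))
                  for m in (0.0, 2.0, 5.0, 10.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_time_reversal_symmetry(self):
        layout = [(12, True, 1, True), (4, True, 1, False), (11, True, 1, True),
                (14, False, -1, True), (9, True, 2, True)]
        st = _states(layout)
        fwd = extract_bouts(st, BoutConfig())
        rev = st.iloc[::-1].reset_index(drop=True)
        rev["t"] = st["t"].to_numpy()
        bwd = extract_bouts(rev, BoutConfig())
        assert sorted(round(b.duration_s, 6) for b in fwd) == \
               sorted(round(b.duration_s, 6) for b in bwd)


class TestGlideExclusion:
    def test_six_second_glide_masked(self):
        glide = np.zeros(100, bool)
        glide[10:40] = True  # 30 samples at 5 Hz = 6 s
        keep = apply_glide_exclusion(glide, RATE, 5.0)
        assert not keep[10:40].any()
        assert keep[:10].all() and keep[40:].all()

    def test_four_second_glide_retained(self):
        glide = np.zeros(100, bool)
        glide[10:30] = True  # 4 s
        assert apply_glide_exclusion(glide, RATE, 5.0).all()

    def test_masked_fraction_small_on_synthetic_flight(self, flock600):
        """Long-glide exclusion removes at most a few percent of flying
        time under the default generator conditions."""
        from wakeflight.signals import classify_flap_glide

        heave = flock600.accel[1]["az"].to_numpy()
        flap20 = classify_flap_glide(heave, 20.0)
        flap5 = flap20.reshape(-1, 4).mean(axis=1) >= 0.5
        keep = apply_glide_exclusion(~flap5, RATE, 5.0)
        assert (~keep).mean() <= 0.03


def _aligned(n, vedba=0.5, flap=1.0, hr=430.0):
    t = np.arange(n) / RATE
    return AlignedStreams(
        bird_id=1,
        table=pd.DataFrame({
            "t": t, "vedba": vedba, "flap_frac": flap,
            "flapping": np.asarray(flap) >= 0.5, "hr": hr,
            "valid": np.ones(n, bool),
        }),
        stream_offset_s=0.0,
    )


class TestSummaries:
    def test_constant_heart_rate(self):
        st = _states([(25, True, 1, True)])
        bouts = extract_bouts(st, BoutConfig())
        out = summarize_bouts(bouts, _aligned(25, hr=430.0), BoutConfig())
        assert out[0].mean_hr == pytest.approx(430.0)
        assert out[0].hr_plausible

    def test_half_flapping_proportion(self):
        n = 30
        al = _aligned(n)
        al.table["flap_frac"] = np.where(np.arange(n) % 2 == 0, 1.0, 0.0)
        st = _states([(n, False, -1, True)])
        out = summarize_bouts(extract_bouts(st, BoutConfig()), al, BoutConfig())
        assert out[0].flap_proportion == pytest.approx(0.5, abs=0.05)

    def test_implausible_heart_rate_flagged(self):
        n = 25
        al = _aligned(n, hr=430.0)
        al.table.loc[15, "hr"] = 900.0  # outside the plausible range
        st = _states([(n, True, 1, True)])
        out = summarize_bouts(extract_bouts(st, BoutConfig()), al, BoutConfig())
        assert not out[0].hr_plausible

    def test_settling_window_excluded_from_hr(self):
        n = 25
        al = _aligned(n, hr=430.0)
        # first second carries stale heart rate; it must not pollute the mean
        al.table.loc[:4, "hr"] = 380.0
        st = _states([(n, True, 1, True)])
        out = summarize_bouts(extract_bouts(st, BoutConfig()), al,
                              BoutConfig(hr_settle_s=1.0))
        assert out[0].mean_hr == pytest.approx(430.0)

    def test_bout_with_no_valid_samples_dropped(self):
        n = 15
        al = _aligned(n)
        al.table["valid"] = False
        st = _states([(n, True, 1, True)])
        out = summarize_bouts(extract_bouts(st, BoutConfig()), al, BoutConfig())
        assert out == []

    def test_hand_enumerated_toy_sequence(self):
        """60 s toy sequence: bout structure enumerated by hand.

        Layout (samples at 5 Hz):
          0-49    in-wake leader 1, valid          -> 10.0 s bout
          50-52   invalid, same flanks            -> bridged
          53-99   in-wake leader 1                 -> merged: 20.0 s total
          100-157 not-in-wake (one contiguous run) -> one 11.6 s bout
          158-197 in-wake leader 2 (8.0 s)         -> kept
          198-299 invalid                          -> nothing
        """
        layout = [
            (50, True, 1, True),
            (3, True, 1, False),
            (47, True, 1, True),
            (8, False, -1, True),
            (50, False, -1, True),
            (40, True, 2, True),
            (102, True, 2, False),
        ]
        st = _states(layout)
        bouts = extract_bouts(st, BoutConfig())
        got = [(b.in_wake, b.leader_id, round(b.duration_s, 1)) for b in bouts]
        assert got == [
            (True, 1, 20.0),
            (False, None, 11.6),
            (True, 2, 8.0),
        ]

    def test_bout_table_round_trip(self):
        st = _states([(25, True, 1, True), (25, False, -1, True)])
        bouts = summarize_bouts(extract_bouts(st, BoutConfig()), _aligned(50), BoutConfig())
        df = bouts_to_frame(bouts, date="d01")
        assert len(df) == 2
        assert set(df["in_wake"]) == {True, False}
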