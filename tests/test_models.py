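"""Statistical layer: transforms, mixed models, paired tests, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wakeflight.models import (
    DbaPositionModel,
    HeartRateModel,
    derived_wingbeat_quantities,
    fit_dba_models,
    hr_back_transform,
    hr_forward_transform,
    hr_percent_difference,
    paired_wingbeat_tests,
)


class TestHrTransform:
    @given(st.floats(100.0, 510.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, hr):
        assert hr_back_transform(hr_forward_transform(hr)) == pytest.approx(hr, abs=1e-9)

    def test_forward_rejects_out_of_domain(self):
        with pytest.raises(ValueError):
            hr_forward_transform(600.0)

    def test_zero_slope_zero_percent(self):
        assert hr_percent_difference(9.0, 0.0) == 0.0

    def test_positive_slope_means_lower_heart_rate(self):
        assert hr_percent_difference(9.0, 0.5) < 0.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            hr_percent_difference(23.0, 0.1)  # 23^2 = 529 > 511.2


class TestDerivedWingbeatQuantities:
    def test_zero_gap_zero_skipped(self):
        out = derived_wingbeat_quantities(3.0, 3.0, 3.6, 3.6)
        assert out["skipped_per_minute"] == 0.0

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            derived_wingbeat_quantities(3.0, -1.0, 3.6, 3.6)


class TestPairedTests:
    def test_refuses_fewer_than_three_pairs(self):
        means = pd.DataFrame({
            "ewbf_not": [3.0, 3.1], "ewbf_in": [2.9, 3.0],
            "flapfreq_not": [3.6, 3.6], "flapfreq_in": [3.7, 3.7],
        })
        with pytest.raises(ValueError):
            paired_wingbeat_tests(means)

    def test_identical_pairs_boundary(self):
        means = pd.DataFrame({
            "ewbf_not": [3.0] * 5, "ewbf_in": [3.0] * 5,
            "flapfreq_not": [3.6] * 5, "flapfreq_in": [3.6] * 5,
        })
        out = paired_wingbeat_tests(means)
        assert out["ewbf_one_sided"]["p"] == 0.5
        assert out["flapping_freq_two_sided"]["p"] == 1.0

    def test_sign_flip_gives_large_one_sided_p(self):
        rng = np.random.default_rng(7)
        not_ = 3.0 + rng.normal(0, 0.05, 10)
        means = pd.DataFrame({
            "ewbf_not": not_, "ewbf_in": not_ + 0.2,  # wrong direction
            "flapfreq_not": [3.6] * 10, "flapfreq_in": [3.62] * 10,
        })
        out = paired_wingbeat_tests(means)
        assert out["ewbf_one_sided"]["p"] > 0.5

    def test_power_at_study_size(self):
        """30 paired birds, true gap 0.09 with s.d. 0.09: the one-sided
        test rejects at alpha=0.05 in >90% of simulated studies."""
        rng = np.random.default_rng(11)
        hits = 0
        reps = 300
        for _ in range(reps):
            diff = rng.normal(0.09, 0.09, 30)
            base = 3.0 + rng.normal(0, 0.1, 30)
            means = pd.DataFrame({
                "ewbf_not": base, "ewbf_in": base - diff,
                "flapfreq_not": 3.6 + rng.normal(0, 0.05, 30),
                "flapfreq_in": 3.6 + rng.normal(0, 0.05, 30),
            })
            if paired_wingbeat_tests(means)["ewbf_one_sided"]["p"] < 0.05:
                hits += 1
        assert hits / reps > 0.9


def _dba_points(rng, effect=-0.0033, n_birds=6, n_dates=2, n_per=300,
                sigma=0.03, base=0.3):
    rows = []
    for b in range(n_birds):
        ab = rng.normal(0, 0.01)
        for d in range(n_dates):
            ad = rng.normal(0, 0.004)
            pos = rng.random(n_per) < 0.5
            y = base + ab + ad + effect * pos + rng.normal(0, sigma, n_per)
            rows.append(pd.DataFrame({
                "bird": b, "date": f"d{d}", "in_wake": pos,
                "vedba": y, "flapping": True,
            }))
    return pd.concat(rows, ignore_index=True)


class TestDbaModel:
    def test_flapping_effect_recovered_statsmodels(self):
        rng = np.random.default_rng(0)
        pts = _dba_points(rng)
        res = DbaPositionModel.from_points(pts, "flapping").fit(backend="statsmodels")
        rep = res.report()
        assert rep.ci_low <= -0.0033 <= rep.ci_high

    def test_backends_agree(self):
        """Dual route: the statsmodels variance-component fit and the
        lme4 fit give the same fixed effects on the same data."""
        rng = np.random.default_rng(1)
        pts = _dba_points(rng, n_birds=5, n_per=200)
        r_sm = DbaPositionModel.from_points(pts, "flapping").fit(backend="statsmodels")
        r_l4 = DbaPositionModel.from_points(pts, "flapping").fit(backend="lme4")
        assert r_l4.params["pos"] == pytest.approx(r_sm.params["pos"], abs=5e-4)
        assert r_l4.bse["pos"] == pytest.approx(r_sm.bse["pos"], rel=0.25)

    def test_gliding_multiplicative_effect_on_log_scale(self):
        rng = np.random.default_rng(2)
        rows = []
        for b in range(6):
            fb = np.exp(rng.normal(0, 0.05))
            for d in range(2):
                pos = rng.random(400) < 0.5
                y = 0.08 * fb * np.where(pos, 1.16, 1.0) * np.exp(rng.normal(0, 0.25, 400))
                rows.append(pd.DataFrame({
                    "bird": b, "date": f"d{d}", "in_wake": pos,
                    "vedba": y, "flapping": False,
                }))
        pts = pd.concat(rows, ignore_index=True)
        rep = DbaPositionModel.from_points(pts, "gliding").fit().report()
        assert rep.response == "log(vedba)"
        assert rep.ci_low <= np.log(1.16) <= rep.ci_high

    def test_subset_selection(self):
        rng = np.random.default_rng(3)
        pts = _dba_points(rng, n_birds=3, n_dates=1, n_per=100)
        m = DbaPositionModel.from_points(pts, "flapping")
        assert m.data["flapping"].all() if "flapping" in m.data else True
        with pytest.raises(ValueError):
            DbaPositionModel.from_points(pts, "hovering")


def _hr_bouts(rng, effects, n_per_bird=250, baselines=None, noise_x=0.12):
    rows = []
    for i, (bird, eff) in enumerate(effects.items()):
        base = (baselines or {}).get(bird, 430.0 - 5 * i)
        pos = rng.random(n_per_bird) < 0.5
        flap = np.clip(rng.normal(0.8, 0.1, n_per_bird) - 0.05 * pos, 0, 1)
        dur = 2.0 + rng.exponential(3.0, n_per_bird)
        hr = base * (1 + eff * pos) * (1 + 0.05 * (flap - 0.8))
        x = np.sqrt(511.2 - hr) + rng.normal(0, noise_x, n_per_bird)
        rows.append(pd.DataFrame({
            "bird": bird, "in_wake": pos, "mean_hr": 511.2 - x**2,
            "flap_prop": flap, "duration": dur, "hr_plausible": True,
        }))
    return pd.concat(rows, ignore_index=True)


class TestHeartRateModel:
    def test_per_bird_effect_recovery(self):
        rng = np.random.default_rng(4)
        bouts = _hr_bouts(rng, {"a": -0.027, "b": -0.027, "c": 0.0, "d": 0.0})
        res = HeartRateModel.from_bouts(bouts).fit()
        tab = res.bootstrap_per_bird(n_boot=150, seed=1)
        assert tab.loc["a", "pct_lower"] <= -2.7 <= tab.loc["a", "pct_upper"]
        assert tab.loc["c", "pct_lower"] <= 0.0 <= tab.loc["c", "pct_upper"]

    def test_flap_coefficient_sign(self):
        """Heart rate rises with flapping, so on the reverse-score
        sqrt scale the flap coefficient is negative."""
        rng = np.random.default_rng(5)
        bouts = _hr_bouts(rng, {"a": 0.0, "b": 0.0, "c": 0.0})
        res = HeartRateModel.from_bouts(bouts).fit()
        assert res.params["flap_z"] < 0

    def test_null_injection_intervals_straddle_zero(self):
        rng = np.random.default_rng(6)
        bouts = _hr_bouts(rng, {"a": 0.0, "b": 0.0, "c": 0.0})
        tab = HeartRateModel.from_bouts(bouts).fit().bootstrap_per_bird(120, seed=2)
        for b in tab.index:
            assert tab.loc[b, "pct_lower"] <= 0.0 <= tab.loc[b, "pct_upper"]

    def test_bootstrap_deterministic(self):
        rng = np.random.default_rng(7)
        bouts = _hr_bouts(rng, {"a": -0.02, "b": 0.0}, n_per_bird=120)
        res = HeartRateModel.from_bouts(bouts).fit()
        t1 = res.bootstrap_per_bird(60, seed=3)
        t2 = res.bootstrap_per_bird(60, seed=3)
        pd.testing.assert_frame_equal(t1, t2)

    def test_intervals_widen_on_subsample(self):
        rng = np.random.default_rng(8)
        bouts = _hr_bouts(rng, {"a": -0.02, "b": -0.02, "c": 0.0}, n_per_bird=400)
        full = HeartRateModel.from_bouts(bouts).fit().bootstrap_per_bird(100, seed=4)
        sub = bouts.sample(frac=0.25, random_state=0)
        quarter = HeartRateModel.from_bouts(sub).fit().bootstrap_per_bird(100, seed=4)
        w_full = (full["pct_upper"] - full["pct_lower"]).mean()
        w_quarter = (quarter["pct_upper"] - quarter["pct_lower"]).mean()
        assert w_quarter > w_full

    def test_duration_shift_invariance(self):
        """Adding a constant to bout duration before z-scoring cannot
        change any estimate."""
        rng = np.random.default_rng(9)
        bouts = _hr_bouts(rng, {"a": -0.02, "b": 0.0})
        r1 = HeartRateModel.from_bouts(bouts).fit()
        shifted = bouts.assign(duration=bouts["duration"] + 100.0)
        r2 = HeartRateModel.from_bouts(shifted).fit()
        pd.testing.assert_series_equal(r1.params, r2.params, atol=1e-6, check_exact=False)

    def test_lrt_detects_position_effect(self):
        rng = np.random.default_rng(10)
        bouts = _hr_bouts(rng, {"a": -0.03, "b": -0.03, "c": -0.03})
        out = HeartRateModel.from_bouts(bouts).fit().lrt_position()
        assert out["p"] < 0.001 and out["df"] == 5

    def test_null_calibration_over_replicates(self):
        """Across repeated null simulations the Wald interval of the
        position fixed effect covers zero at roughly its nominal rate
        (checked at reduced replicates)."""
        rng = np.random.default_rng(14)
        covered = 0
        reps = 10
        for _ in range(reps):
            bouts = _hr_bouts(rng, {"a": 0.0, "b": 0.0, "c": 0.0}, n_per_bird=150)
            res = HeartRateModel.from_bouts(bouts).fit()
            ci = res.conf_int().loc["pos"]
            covered += ci["lower"] <= 0.0 <= ci["upper"]
        assert covered >= reps - 2

    def test_rejects_single_bird(self):
        rng = np.random.default_rng(11)
        bouts = _hr_bouts(rng, {"a": 0.0})
        with pytest.raises(ValueError, match="2 birds"):
            HeartRateModel.from_bouts(bouts)

    def test_out_of_domain_heart_rates_dropped(self):
        rng = np.random.default_rng(12)
        bouts = _hr_bouts(rng, {"a": 0.0, "b": 0.0})
        bouts.loc[:3, "mean_hr"] = 515.0
        with pytest.warns(UserWarning, match="rejected"):
            m = HeartRateModel.from_bouts(bouts)
        assert (m.data["mean_hr"] < 511.2).all()

    def test_summary_renders(self):
        rng = np.random.default_rng(13)
        res = HeartRateModel.from_bouts(_hr_bouts(rng, {"a": 0.0, "b": 0.0})).fit()
        text = res.summary()
        assert "Per-bird" in text and "flap_z" in text
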