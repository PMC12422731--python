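import numpy as np
import pytest

import circalab as cl
from circalab.activity import (OnsetSeries, actogram_matrix,
                               count_activity_bouts, detect_onsets,
                               onset_variability, segment_activity_bouts,
                               windowed_activity)
from circalab.io import ActivityTrace
from oracles import brute_activity_bouts


def minute_trace(x, schedule=None):
    return ActivityTrace(0.0, 1.0, np.asarray(x, dtype=float), schedule=schedule)


class TestDetectOnsets:
    def test_jitter_free_ld_onsets_at_lights_off(self, quiet_wt, ld10):
        tr = cl.simulate_activity(quiet_wt, ld10)
        onsets = detect_onsets(tr)
        assert onsets.n_valid == 10
        np.testing.assert_array_equal(onsets.onset_min % 1440, 720.0)

    def test_dd_fitted_drift_matches_tau(self):
        # tau 23.6 h: onsets drift -24 min/day in time of day
        slopes = []
        for seed in range(5):
            p = cl.make_params("wt_like", seed=seed, onset_jitter_min=5,
                               tau_hours=23.6)
            tr = cl.simulate_activity(p, cl.Protocol([cl.DD(10)]))
            slopes.append(detect_onsets(tr, 23.6).fit().drift_min_per_day)
        assert np.mean(slopes) == pytest.approx(-24.0, abs=2.0)

    def test_all_zero_trace_gives_missing_onsets_without_crash(self):
        onsets = detect_onsets(minute_trace(np.zeros(10 * 1440)))
        assert onsets.n_valid == 0

    def test_needs_three_days(self):
        with pytest.raises(ValueError, match="3 days"):
            detect_onsets(minute_trace(np.zeros(2 * 1440)))


class TestOnsetVariability:
    def test_perfectly_linear_onsets_have_zero_variability(self):
        onsets = OnsetSeries(np.arange(10), 700.0 + 1432.0 * np.arange(10))
        assert onset_variability(onsets) == pytest.approx(0.0, abs=1e-9)

    def test_translation_and_slope_invariance(self, rng):
        base = 720.0 + 1440.0 * np.arange(10) + rng.normal(0, 20, 10)
        onsets = OnsetSeries(np.arange(10), base)
        v0 = onset_variability(onsets)
        assert onset_variability(onsets.shifted(500.0)) == pytest.approx(v0)
        tilted = OnsetSeries(np.arange(10), base + 13.0 * np.arange(10))
        assert onset_variability(tilted) == pytest.approx(v0)

    def test_jitter_recovery_quick(self):
        est = []
        for seed in range(20):
            p = cl.make_params("wt_like", seed=seed, onset_jitter_min=25.0)
            tr = cl.simulate_activity(p, cl.Protocol([cl.LD(12)]))
            onsets = detect_onsets(tr)
            sub = OnsetSeries(onsets.days[2:12], onsets.onset_min[2:12])
            est.append(onset_variability(sub))
        assert np.mean(est) == pytest.approx(25.0, rel=0.30)

    def test_missing_day_tolerated_but_five_required(self):
        o = 720.0 + 1440.0 * np.arange(10)
        o[3] = np.nan
        assert onset_variability(OnsetSeries(np.arange(10), o)) == pytest.approx(0, abs=1e-9)
        with pytest.raises(ValueError, match="5"):
            onset_variability(OnsetSeries(np.arange(4), o[:4]))


class TestActivityBouts:
    def test_single_block_is_one_bout(self):
        x = np.zeros(1440)
        x[300:500] = 10.0
        assert count_activity_bouts(minute_trace(x)) == 1.0

    def test_20min_gap_merges_21min_gap_splits(self):
        for gap, expect in ((20, 1), (21, 2)):
            x = np.zeros(1440)
            x[100:200] = 10.0
            x[200 + gap:300 + gap] = 10.0
            assert count_activity_bouts(minute_trace(x)) == expect

    def test_scaling_above_threshold_leaves_bouts_unchanged(self, rng):
        x = rng.choice([0.0, 5.0, 40.0], size=1440, p=[0.7, 0.2, 0.1])
        a = segment_activity_bouts(minute_trace(x))
        b = segment_activity_bouts(minute_trace(x * 10))
        assert [(u.start_min, u.end_min) for u in a] == \
               [(u.start_min, u.end_min) for u in b]

    def test_bout_count_monotone_in_max_gap(self, rng):
        x = rng.choice([0.0, 10.0], size=2880, p=[0.8, 0.2])
        tr = minute_trace(x)
        counts = [count_activity_bouts(tr, max_gap_min=g) for g in (5, 21, 60)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_matches_brute_force_on_random_traces(self, rng):
        for _ in range(300):
            n = int(rng.integers(60, 600))
            x = rng.choice([0.0, 1.0, 3.0, 12.0], size=n,
                           p=[0.55, 0.15, 0.1, 0.2])
            got = [(b.start_min, b.end_min)
                   for b in segment_activity_bouts(minute_trace(x))]
            assert got == brute_activity_bouts(x)

    def test_subthreshold_minutes_inside_bout_counted_in_total(self):
        x = np.zeros(1440)
        x[100:110] = 10.0
        x[110:115] = 1.0          # below threshold, inside the bout
        x[115:120] = 10.0
        bouts = segment_activity_bouts(minute_trace(x))
        assert len(bouts) == 1
        assert bouts[0].total_counts == pytest.approx(10 * 10 + 5 * 1 + 5 * 10)


class TestWindowedActivity:
    def test_uniform_rate_zt0_3_gives_1800_counts(self):
        sched, _ = cl.Protocol([cl.LD(3)]).build_schedule()
        tr = minute_trace(np.full(3 * 1440, 10.0), schedule=sched)
        assert windowed_activity(tr, (0, 3)) == pytest.approx(1800.0)

    def test_night_only_activity_leaves_light_window_empty(self, quiet_wt):
        p = cl.make_params("wt_like", seed=0, onset_jitter_min=0, rest_rate=0.0)
        tr = cl.simulate_activity(p, cl.Protocol([cl.LD(5)]))
        assert windowed_activity(tr, (0, 3)) == 0.0

    def test_day_percentage_cross_checks_direct_summation(self):
        p = cl.make_params("ko_like", seed=4)
        tr = cl.simulate_activity(p, cl.Protocol([cl.LD(5)]))
        day = windowed_activity(tr, (0, 12))
        total = windowed_activity(tr, (0, 24))
        assert total == pytest.approx(np.nansum(tr.counts) / 5)
        assert 0 < 100 * day / total < 100

    def test_dd_trace_without_schedule_rejected(self):
        with pytest.raises(ValueError, match="schedule"):
            windowed_activity(minute_trace(np.ones(1440)), (0, 3))


def test_actogram_matrix_shapes():
    tr = minute_trace(np.arange(5 * 1440, dtype=float))
    single = actogram_matrix(tr, double=False)
    double = actogram_matrix(tr)
    assert single.shape == (5, 1440)
    assert double.shape == (5, 2880)
    np.testing.assert_array_equal(double[0, 1440:], single[1])
    assert np.isnan(double[-1, 1440:]).all()
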