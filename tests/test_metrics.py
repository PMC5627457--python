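import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sociotrack import metrics
from sociotrack.events import Bout, Interval, Transition
from sociotrack.metrics import (InputError, binned_time,
                                bout_duration_histogram,
                                interval_duration_histogram,
                                open_field_metrics, phase_summary,
                                pool_group, rdi, rdi_by_intervals,
                                summarize_session, transition_dynamics)
from sociotrack.tracking import FrameObservation, TrackingResult


def random_bouts(rng, session_length_s=300.0, n=None):
    n = n if n is not None else int(rng.integers(0, 40))
    starts = np.sort(rng.uniform(0, session_length_s, n))
    bouts = []
    for i, s in enumerate(starts):
        limit = starts[i + 1] if i + 1 < n else session_length_s
        if limit - s <= 2e-3:
            continue
        dur = rng.uniform(1e-3, limit - s)
        bouts.append(Bout(int(rng.integers(1, 3)), s, s + dur))
    return bouts


class TestBinnedTime:
    def test_overlap_split(self):
        out = binned_time([Bout(1, 25.0, 45.0)], session_length_s=60.0)
        np.testing.assert_allclose(out[1], [0.0, 15.0, 5.0])

    def test_no_bouts_all_zero(self):
        out = binned_time([], session_length_s=300.0)
        assert not out[1].any() and not out[2].any()

    def test_conservation_on_random_bout_sets(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            bouts = random_bouts(rng)
            out = binned_time(bouts, session_length_s=300.0)
            for stim in (1, 2):
                total = sum(b.duration_s for b in bouts
                            if b.stimulus == stim)
                assert out[stim].sum() == pytest.approx(total, abs=1e-9)

    def test_truncated_last_bin(self):
        out = binned_time([Bout(1, 0.0, 50.0)], session_length_s=50.0)
        assert out[1].size == 3
        assert out[1].sum() == pytest.approx(50.0)


class TestRdi:
    def test_closed_forms(self):
        assert rdi(10, 10) == 0
        assert rdi(10, 0) == 1
        assert rdi(3, 1) == pytest.approx(0.5)
        assert rdi(1, 3) == pytest.approx(-0.5)
        assert rdi(1, 3, signed=False) == pytest.approx(0.5)

    def test_undefined_when_no_investigation(self):
        assert rdi(0, 0) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rdi(-1, 2)

    @settings(derandomize=True, max_examples=100)
    @given(a=st.floats(0, 1e4), b=st.floats(0, 1e4))
    def test_antisymmetry_and_range(self, a, b):
        if a + b == 0:
            return
        assert rdi(a, b) == pytest.approx(-rdi(b, a))
        assert -1 <= rdi(a, b) <= 1
        assert rdi(a, b, signed=False) == pytest.approx(abs(rdi(a, b)))

    def test_by_intervals(self):
        ivs = [Interval(1, 0, 30), Interval(2, 40, 50),
               Interval(1, 100, 102), Interval(2, 150, 160)]
        # prolonged (> 20 s): stim1 30 s, stim2 none -> undefined denom?
        assert rdi_by_intervals(ivs) == pytest.approx(1.0)
        assert rdi_by_intervals([Interval(1, 0, 5)]) is None

    def test_by_intervals_closed_form(self):
        ivs = [Interval(1, 0, 30), Interval(2, 50, 60.0)]
        # stim1 prolonged total 30; stim2 none (10 s < 20)
        assert rdi_by_intervals(ivs, prolonged_threshold_s=5) == \
            pytest.approx((30 - 10) / 40)


class TestDurationHistograms:
    def test_bout_category_boundaries(self):
        out = bout_duration_histogram(
            [Bout(1, 0, 6.0), Bout(1, 10, 29.5), Bout(2, 40, 59.0)])
        assert out[1][0] == pytest.approx(6.0)    # 6.0 s is "short" (<= 6)
        assert out[1][-1] == pytest.approx(19.5)  # 19.5 s is "long" (> 19)
        assert out[2][2] == pytest.approx(19.0)   # exactly 19 s: (12.5, 19]
        assert out[2][-1] == pytest.approx(0.0)

    def test_bout_conservation(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            bouts = random_bouts(rng)
            out = bout_duration_histogram(bouts)
            for stim in (1, 2):
                total = sum(b.duration_s for b in bouts
                            if b.stimulus == stim)
                assert out[stim].sum() == pytest.approx(total, abs=1e-9)

    def test_bad_edges_rejected(self):
        with pytest.raises(InputError):
            bout_duration_histogram([], edges_s=[6, 6, 19])

    def test_interval_categories_and_counts(self):
        ivs = [Interval(1, 0, 5), Interval(1, 10, 35), Interval(2, 50, 65)]
        out = interval_duration_histogram(ivs)
        assert out[1]["count"][0] == 1    # 5 s short
        assert out[1]["count"][-1] == 1   # 25 s long
        assert out[2]["count"][1] == 1    # 15 s middle
        assert out[1]["count"].sum() + out[2]["count"].sum() == len(ivs)
        assert out[1]["time"].sum() == pytest.approx(30.0)


class TestTransitionDynamics:
    def test_bin_counts(self):
        trs = [Transition(t, 1, 2) for t in (10.0, 30.0, 50.0)]
        out = transition_dynamics(trs, session_length_s=300.0)
        np.testing.assert_array_equal(out["bin_counts"][:4], [1, 1, 1, 0])

    def test_empty(self):
        out = transition_dynamics([], session_length_s=300.0)
        assert out["bin_counts"].sum() == 0
        assert out["total"] == 0

    def test_window_totals_partition(self):
        rng = np.random.default_rng(2)
        trs = [Transition(float(t), 1, 2)
               for t in np.sort(rng.uniform(0, 300, 40))]
        out = transition_dynamics(trs, 300.0)
        assert sum(out["window_totals"].values()) == out["total"]


class TestPhaseSummary:
    def test_all_bouts_in_exploration(self):
        bouts = [Bout(1, 10, 15), Bout(2, 50, 80)]
        out = phase_summary(bouts, [])
        inter = out["interaction"]
        assert inter["stim1"]["total_s"] == 0
        assert inter["stim2"]["total_s"] == 0

    def test_short_middle_long_partition(self):
        rng = np.random.default_rng(9)
        bouts = random_bouts(rng, n=30)
        out = phase_summary(bouts, [])
        for win in out.values():
            for stim in ("stim1", "stim2"):
                s = win[stim]
                assert s["short_s"] + s["middle_s"] + s["long_s"] == \
                    pytest.approx(s["total_s"], abs=1e-9)

    def test_bout_assigned_by_start(self):
        # starts at 119, runs into the interaction window: stays exploration
        out = phase_summary([Bout(1, 119.0, 140.0)], [])
        assert out["exploration"]["stim1"]["total_s"] == pytest.approx(21.0)
        assert out["interaction"]["stim1"]["total_s"] == 0

    def test_overlapping_windows_rejected(self):
        with pytest.raises(InputError):
            phase_summary([], [], exploration_window=(0, 150),
                          interaction_window=(120, 300))


def _track_from_path(points, config, valid=None):
    obs = []
    for i, p in enumerate(points):
        v = True if valid is None else valid[i]
        obs.append(FrameObservation(i, i / config.frame_rate,
                                    tuple(p) if v else None, None, None,
                                    0, v))
    return TrackingResult(obs, "body", config)


class TestOpenField:
    def test_stationary(self, config):
        tr = _track_from_path([(100.0, 100.0)] * 100, config)
        out = open_field_metrics(tr, config)
        assert out["total_distance_cm"] == 0.0

    def test_straight_path_known_length(self, config):
        # 100 steps of 1 px along x: 99 px total
        pts = [(50.0 + i, 100.0) for i in range(100)]
        out = open_field_metrics(_track_from_path(pts, config), config)
        assert out["total_distance_cm"] == pytest.approx(
            99.0 / config.px_per_cm, rel=1e-9)

    def test_steps_over_invalid_frames_skipped(self, config):
        pts = [(50.0, 100.0), (60.0, 100.0), (300.0, 100.0),
               (310.0, 100.0)]
        valid = [True, True, False, True]
        out = open_field_metrics(_track_from_path(pts, config, valid),
                                 config)
        assert out["total_distance_cm"] == pytest.approx(
            10.0 / config.px_per_cm)

    def test_center_ratio_degenerate(self, config):
        x, y, w, h = config.arena_rect
        center = (x + w / 2, y + h / 2)
        out = open_field_metrics(
            _track_from_path([center] * 50, config), config)
        assert out["center_periphery_ratio"] is None
        assert out["center_time_s"] == pytest.approx(50 / config.frame_rate)

    def test_center_region_is_quarter_area(self, config):
        # corner point is periphery, center point is center
        x, y, w, h = config.arena_rect
        pts = [(x + 1, y + 1), (x + w / 2, y + h / 2)] * 30
        out = open_field_metrics(_track_from_path(pts, config), config)
        assert out["center_periphery_ratio"] == pytest.approx(1.0)


def _summary(rng, session="s", n_bouts=20):
    bouts = random_bouts(rng, n=n_bouts)
    ivs = []
    trans = [Transition(b.start_s, 1, 2) for b in bouts[1::3]]
    return summarize_session(bouts, ivs, trans, 300.0, session=session)


class TestPooling:
    def test_identical_summaries_sem_zero(self):
        rng = np.random.default_rng(21)
        s = _summary(rng)
        out = pool_group([s, s])
        assert out["rdi_time_sem"] == pytest.approx(0.0)
        assert np.allclose(out["binned_sem_stim1"], 0.0)

    def test_perfect_linear_pairs(self):
        rng = np.random.default_rng(22)
        summaries = [_summary(rng, session=f"s{i}") for i in range(6)]
        for i, s in enumerate(summaries):
            s.rdi_time = 0.1 * i
            # total_transitions linear in rdi_time
            s.total_transitions = 2 * i + 3
        out = pool_group(summaries,
                         scatter_pairs=[("total_transitions", "rdi_time")])
        corr = out["correlations"]["total_transitions~rdi_time"]
        assert corr["r"] == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        xs = [1.0, 2.0, 4.0, 5.0, 8.0]
        ys = [2.0, 3.0, 3.0, 6.0, 7.0]
        n = 5
        sx, sy = sum(xs), sum(ys)
        sxx = sum(v * v for v in xs)
        syy = sum(v * v for v in ys)
        sxy = sum(a * b for a, b in zip(xs, ys))
        expect = ((n * sxy - sx * sy)
                  / np.sqrt((n * sxx - sx**2) * (n * syy - sy**2)))
        rng = np.random.default_rng(23)
        summaries = [_summary(rng, session=f"s{i}") for i in range(5)]
        for s, x, y in zip(summaries, xs, ys):
            s.rdi_time = y
            s.total_transitions = x
        out = pool_group(summaries,
                         scatter_pairs=[("total_transitions", "rdi_time")])
        assert out["correlations"]["total_transitions~rdi_time"]["r"] == \
            pytest.approx(expect)

    def test_missing_values_excluded(self):
        rng = np.random.default_rng(24)
        summaries = [_summary(rng, session=f"s{i}") for i in range(4)]
        summaries[0].rdi_time = None
        out = pool_group(summaries)
        vals = [s.rdi_time for s in summaries[1:]]
        assert out["rdi_time_mean"] == pytest.approx(np.mean(vals))

    def test_requires_two_sessions(self):
        rng = np.random.default_rng(25)
        with pytest.raises(InputError):
            pool_group([_summary(rng)])

    def test_inconsistent_binning_rejected(self):
        rng = np.random.default_rng(26)
        a = _summary(rng)
        b = _summary(rng)
        b.bin_width_s = 10.0
        with pytest.raises(InputError):
            pool_group([a, b])


class TestSessionSummaryInvariants:
    def test_binned_sums_to_total(self):
        rng = np.random.default_rng(30)
        for _ in range(20):
            bouts = random_bouts(rng)
            s = summarize_session(bouts, [], [], 300.0)
            for stim in (1, 2):
                assert s.binned[stim].sum() == pytest.approx(
                    s.total_time[stim], abs=1e-9)
                assert s.bout_hist[stim].sum() == pytest.approx(
                    s.total_time[stim], abs=1e-9)
            if s.rdi_time is not None:
                assert -1 <= s.rdi_time <= 1
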