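import math

import numpy as np
import pytest

from sociotrack import events, synthetic, tracking
from sociotrack.synthetic import _ellipse_mask
from sociotrack.tracking import (FitError, InputError, body_contact,
                                 fit_body_ellipse, head_contact,
                                 mask_centroid, remove_cable,
                                 resolve_head_tail, segment_subject, track)


def blank(config, render_params):
    h, w = render_params.frame_shape
    return np.full((h, w), render_params.background_gray, dtype=np.uint8)


def draw_ellipse(frame, center, heading, a, b, gray):
    mask = _ellipse_mask(frame.shape, center, heading, a, b)
    frame[mask] = gray
    return mask


class TestSegmentation:
    def test_uniform_white_frame(self, config, render_params):
        frame = blank(config, render_params)
        assert segment_subject(frame, config.detection_threshold_low,
                               config.min_blob_area_px, config) is None

    def test_rendered_ellipse_area_recovered(self, config, render_params):
        frame = blank(config, render_params)
        painted = draw_ellipse(frame, (160, 120), (1.0, 0.0), 14, 7, 40)
        mask = segment_subject(frame, config.detection_threshold_low,
                               config.min_blob_area_px, config)
        assert mask is not None
        assert abs(mask.sum() - painted.sum()) <= 0.05 * painted.sum()

    def test_small_speck_filtered(self, config, render_params):
        frame = blank(config, render_params)
        draw_ellipse(frame, (160, 120), (1.0, 0.0), 14, 7, 40)
        frame[50:53, 50:53] = 40  # 9-px speck < min_blob_area_px
        mask = segment_subject(frame, config.detection_threshold_low,
                               config.min_blob_area_px, config)
        assert not mask[50:53, 50:53].any()

    def test_outside_arena_ignored(self, config, render_params):
        frame = blank(config, render_params)
        frame[0:5, :] = 0  # dark band outside the arena rect
        assert segment_subject(frame, config.detection_threshold_low,
                               config.min_blob_area_px, config) is None

    def test_frame_config_mismatch(self, config):
        with pytest.raises(InputError):
            segment_subject(np.zeros((10, 10), np.uint8), 90, 10, config)


class TestEllipseFit:
    @pytest.mark.parametrize("angle_deg", [0, 37, 90, 142])
    def test_orientation_recovered(self, angle_deg):
        th = math.radians(angle_deg)
        heading = (math.cos(th), math.sin(th))
        mask = _ellipse_mask((240, 320), (160, 120), heading, 20, 8)
        _, (a, b), axis, endpoints = fit_body_ellipse(mask)
        got = math.degrees(math.atan2(axis[1], axis[0])) % 180
        diff = min(abs(got - angle_deg % 180),
                   180 - abs(got - angle_deg % 180))
        assert diff < 2.0

    def test_endpoints_near_rendered_tips(self):
        th = math.radians(37)
        heading = np.array([math.cos(th), math.sin(th)])
        center = np.array([160.0, 120.0])
        mask = _ellipse_mask((240, 320), center, heading, 20, 8)
        *_, endpoints = fit_body_ellipse(mask)
        tips = [center + 20 * heading, center - 20 * heading]
        for tip in tips:
            d = min(np.hypot(*(np.array(e) - tip)) for e in endpoints)
            assert d <= 2.0

    def test_degenerate_masks_raise(self):
        single = np.zeros((10, 10), bool)
        single[5, 5] = True
        with pytest.raises(FitError):
            fit_body_ellipse(single)
        line = np.zeros((10, 10), bool)
        line[5, 2:8] = True
        with pytest.raises(FitError):
            fit_body_ellipse(line)

    def test_circular_mask_gives_antipodal_endpoints(self):
        mask = _ellipse_mask((100, 100), (50, 50), (1.0, 0.0), 10, 10)
        center, axes, axis, (e1, e2) = fit_body_ellipse(mask)
        mid = (np.array(e1) + np.array(e2)) / 2
        np.testing.assert_allclose(mid, center, atol=0.5)


class TestHeadTail:
    def _masks(self):
        low = _ellipse_mask((100, 100), (50, 50), (1.0, 0.0), 15, 6)
        high = low.copy()
        high[48:52, 20:36] = True  # tail pixels to the left (rump side)
        return low, high

    def test_tail_evidence_picks_far_endpoint(self):
        low, high = self._masks()
        *_, endpoints = fit_body_ellipse(low)
        head = resolve_head_tail(endpoints, high, low)
        assert head is not None
        assert head[0] > 50  # nose is on the right, away from the tail

    def test_no_tail_falls_back_to_previous_head(self):
        low, _ = self._masks()
        *_, endpoints = fit_body_ellipse(low)
        head = resolve_head_tail(endpoints, low, low,
                                 previous_head=(70.0, 50.0))
        assert head[0] > 50
        head = resolve_head_tail(endpoints, low, low,
                                 previous_head=(30.0, 50.0))
        assert head[0] < 50

    def test_no_information_undetermined(self):
        low, _ = self._masks()
        *_, endpoints = fit_body_ellipse(low)
        assert resolve_head_tail(endpoints, low, low) is None


class TestContact:
    def test_far_from_zones(self, config):
        boundary = np.array([[160.0, 120.0], [165.0, 125.0]])
        assert body_contact(boundary, config) == events.NONE

    def test_point_on_zone(self, config):
        seg = next(iter(config.stimulus_zones.values()))
        mid = (np.array(seg[0]) + np.array(seg[1])) / 2
        assert body_contact(np.array([mid]), config) == events.STIM1

    def test_closed_inequality_at_contact_distance(self):
        # axis-aligned zones so the boundary distance is float-exact
        from sociotrack.arena import ArenaConfig
        cfg = ArenaConfig(
            arena_rect=(0, 0, 300, 220), px_per_cm=8.0,
            stimulus_zones={"stim1": ((10.0, 0.0), (50.0, 0.0)),
                            "stim2": ((250.0, 220.0), (290.0, 220.0))})
        cd = cfg.contact_distance_px
        assert body_contact(np.array([[30.0, cd]]), cfg) == events.STIM1
        assert body_contact(np.array([[30.0, cd + 0.01]]), cfg) == \
            events.NONE

    def test_head_contact_is_point_based(self, config):
        seg = config.stimulus_zones["stim1"]
        mid = tuple((np.array(seg[0]) + np.array(seg[1])) / 2)
        assert head_contact(mid, config) == events.STIM1
        assert head_contact((160.0, 120.0), config) == events.NONE

    def test_rump_touch_differs_between_algorithms(self, config):
        """Body boundary on a zone scores body contact but not head
        contact when the head is elsewhere."""
        seg = config.stimulus_zones["stim2"]
        mid = (np.array(seg[0]) + np.array(seg[1])) / 2
        boundary = np.vstack([mid, [160.0, 120.0]])
        assert body_contact(boundary, config) == events.STIM2
        assert head_contact((160.0, 120.0), config) == events.NONE


class TestRemoveCable:
    def test_cable_free_mask_nearly_unchanged(self):
        mask = _ellipse_mask((100, 100), (50, 50), (1.0, 0.0), 15, 7)
        out = remove_cable(mask)
        change = abs(int(out.sum()) - int(mask.sum())) / mask.sum()
        assert change < 0.15

    def test_cable_removed_centroid_restored(self):
        body = _ellipse_mask((120, 160), (80, 60), (1.0, 0.0), 14, 7)
        with_cable = body.copy()
        with_cable[58:60, 0:70] = True  # 2-px cable to the frame edge
        out = remove_cable(with_cable)
        cx_true, cy_true = mask_centroid(body)
        cx, cy = mask_centroid(out)
        assert np.hypot(cx - cx_true, cy - cy_true) <= 3.0

    def test_nothing_left_returns_none(self):
        thin = np.zeros((50, 50), bool)
        thin[25, 5:45] = True
        assert remove_cable(thin) is None


class TestTrack:
    def test_empty_arena_all_invalid(self, config, render_params):
        frames = [blank(config, render_params)] * 10
        result = track(iter(frames), config, "body")
        assert all(not o.valid for o in result.observations)
        assert result.invalid_fraction == 1.0
        labels = events.labels_from_track(result)
        assert labels.total_time(1) == 0 and labels.total_time(2) == 0

    def test_deterministic(self, config, sp_video):
        _, frames, _ = sp_video
        sub = frames[:120]
        a = track(iter(sub), config, "body").to_frame()
        b = track(iter(sub), config, "body").to_frame()
        assert a.equals(b)

    def test_unknown_algorithm(self, config):
        with pytest.raises(ValueError):
            track(iter([]), config, "magic")

    def test_head_contact_subset_of_body(self, config, sp_video):
        """Whenever the head algorithm scores contact, the body algorithm
        scores the same stimulus on that frame."""
        _, frames, _ = sp_video
        sub = frames[:600]
        body = track(iter(sub), config, "body")
        head = track(iter(sub), config, "head")
        for ob, oh in zip(body.observations, head.observations):
            if oh.contact != events.NONE:
                assert ob.contact == oh.contact

    def test_body_and_wired_agree_without_cable(self, config, sp_video):
        _, frames, _ = sp_video
        sub = frames[:600]
        body = track(iter(sub), config, "body")
        wired = track(iter(sub), config, "wired_body")
        agree = np.mean([a.contact == b.contact for a, b in
                         zip(body.observations, wired.observations)])
        assert agree >= 0.99

    def test_per_frame_csv_round_trip(self, config, sp_video, tmp_path):
        from sociotrack.tracking import track_from_csv
        _, frames, _ = sp_video
        result = track(iter(frames[:120]), config, "body")
        path = tmp_path / "frames.csv"
        result.write_csv(path)
        loaded = track_from_csv(path, config)
        assert [o.contact for o in loaded.observations] == \
            [o.contact for o in result.observations]
        assert loaded.to_frame()["cx_px"].equals(
            result.to_frame()["cx_px"])
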