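import numpy as np
import pytest

import adpt
from adpt.decode import (
    build_identity_map,
    decode_single,
    decode_social,
    identity_of_frame,
    temporal_identity_correction,
)
from adpt.targets import make_baf, make_heatmap_and_locref, make_lrss

from conftest import random_keypoint_frame


class TestDecodeSingle:
    def test_encode_decode_round_trip(self, skeleton, config, rng):
        for _ in range(100):
            frame = random_keypoint_frame(rng, skeleton)
            tm = make_heatmap_and_locref(frame, skeleton, config)
            dets = decode_single({"heatmap": tm.heatmaps, "locref": tm.locref}, config)
            gt = frame.instances[0].keypoints
            for d in dets:
                assert d.confidence == 1.0 and d.detected
                err = np.hypot(d.x - gt[d.keypoint_index, 0], d.y - gt[d.keypoint_index, 1])
                assert err <= 1e-6 * config.stride

    def test_grid_aligned_keypoint_zero_locref(self, skeleton, config):
        heat = np.zeros((5, 8, 8))
        heat[0, 2, 3] = 1.0
        dets = decode_single({"heatmap": heat, "locref": np.zeros((10, 8, 8))}, config)
        assert (dets[0].x, dets[0].y) == (3 * 8, 2 * 8)

    def test_confidence_at_cutoff_is_not_detected(self, skeleton, config):
        heat = np.zeros((1, 8, 8))
        heat[0, 1, 1] = 0.15
        dets = decode_single({"heatmap": heat, "locref": np.zeros((2, 8, 8))}, config)
        assert not dets[0].detected and dets[0].confidence == pytest.approx(0.15)
        heat[0, 1, 1] = 0.2  # exactly at the cutoff still counts as a miss
        assert not decode_single({"heatmap": heat, "locref": np.zeros((2, 8, 8))}, config)[0].detected

    def test_all_zero_channel_flagged_invalid(self, config):
        dets = decode_single(
            {"heatmap": np.zeros((1, 8, 8)), "locref": np.zeros((2, 8, 8))}, config
        )
        assert not dets[0].valid and dets[0].confidence == 0.0 and not dets[0].detected

    def test_global_scale_rescaling(self, skeleton):
        cfg = adpt.Config(global_scale=0.5, sigma=1.0, locref_radius=1.5)
        heat = np.zeros((1, 8, 8))
        heat[0, 2, 2] = 1.0
        locref = np.zeros((2, 8, 8))
        locref[0, 2, 2] = 3.0
        dets = decode_single({"heatmap": heat, "locref": locref}, cfg)
        assert dets[0].x == pytest.approx((2 * 8 + 3.0) / 0.5)


class TestIdentityOfFrame:
    def test_single_label_map(self, config):
        p = np.zeros((4, 8, 8))
        p[2, 1:3, 1:3] = 1.0
        assert identity_of_frame(p, config) == 2

    def test_majority_wins(self, config):
        p = np.zeros((3, 10, 10))
        p[1].flat[:60] = 1.0
        p[2].flat[:40] = 1.0
        assert identity_of_frame(p, config) == 1

    def test_tie_goes_to_lowest_label(self, config):
        p = np.zeros((3, 4, 4))
        p[1, 0, :2] = 1.0
        p[2, 1, :2] = 1.0
        assert identity_of_frame(p, config) == 1

    def test_background_only_returns_unknown(self, config):
        p = np.zeros((3, 4, 4))
        p[0] = 1.0
        assert identity_of_frame(p, config) is None


class TestIdentityMap:
    def test_single_instance_exact_targets_cover_footprint(self, skeleton, config):
        frame = adpt.generate_scene(adpt.SceneSpec(seed=1))
        lrss = make_lrss(frame, skeleton, config, identity_aware=True)
        baf = make_baf(frame, skeleton, config)
        imap = build_identity_map(lrss, baf, config)
        assert np.array_equal(imap.labels != 0, lrss != 0)
        assert np.all(imap.labels[lrss != 0] == 1)

    def test_two_disjoint_bodies_keep_their_identities(self, skeleton, pair_config):
        frame = adpt.generate_scene(adpt.SceneSpec(image_size=(96, 96), n_animals=2, seed=8))
        lrss = make_lrss(frame, skeleton, pair_config, identity_aware=True)
        baf = make_baf(frame, skeleton, pair_config)
        imap = build_identity_map(lrss, baf, pair_config)
        # exhaustive per-pixel check against the LRSS labels themselves
        assert np.array_equal(imap.labels, lrss)

    def test_zero_baf_degenerates_to_lrss(self, skeleton, config):
        frame = adpt.generate_scene(adpt.SceneSpec(seed=3))
        lrss = make_lrss(frame, skeleton, config, identity_aware=True)
        imap = build_identity_map(lrss, np.zeros((2,) + lrss.shape), config)
        assert np.array_equal(imap.labels, lrss)

    def test_out_of_map_centers_are_clamped_and_counted(self, config):
        lrss = np.zeros((4, 4), dtype=np.int64)
        lrss[0, 0] = 1
        baf = np.zeros((2, 4, 4))
        baf[0, 0, 0] = 10.0  # points far left of the map
        imap = build_identity_map(lrss, baf, config)
        assert imap.n_clamped == 1


class TestDecodeSocial:
    def test_single_instance_reduces_to_decode_single(self, skeleton, config, rng):
        frame = random_keypoint_frame(rng, skeleton, margin=12)
        tm = make_heatmap_and_locref(frame, skeleton, config)
        lrss = make_lrss(frame, skeleton, config, identity_aware=True)
        baf = make_baf(frame, skeleton, config)
        imap = build_identity_map(lrss, baf, config)
        heads = {"heatmap": tm.heatmaps, "locref": tm.locref}
        per_id, _ = decode_social(heads, imap, config)
        singles = decode_single(heads, config)
        assert set(per_id) == {1}
        by_k = {d.keypoint_index: d for d in per_id[1]}
        for s in singles:
            d = by_k[s.keypoint_index]
            assert (d.x, d.y, d.confidence) == (s.x, s.y, s.confidence)

    def test_two_instances_recovered_with_correct_identities(self, skeleton, pair_config):
        for seed in range(20):
            frame = adpt.generate_scene(
                adpt.SceneSpec(image_size=(96, 96), n_animals=2, seed=seed)
            )
            tm = make_heatmap_and_locref(frame, skeleton, pair_config)
            lrss = make_lrss(frame, skeleton, pair_config, identity_aware=True)
            baf = make_baf(frame, skeleton, pair_config)
            imap = build_identity_map(lrss, baf, pair_config)
            per_id, _ = decode_social(
                {"heatmap": tm.heatmaps, "locref": tm.locref}, imap, pair_config
            )
            for inst in frame.instances:
                dets = {d.keypoint_index: d for d in per_id[inst.identity]}
                assert len(dets) == skeleton.n_keypoints
                for k, d in dets.items():
                    err = np.hypot(d.x - inst.keypoints[k, 0], d.y - inst.keypoints[k, 1])
                    assert err <= 1e-6 * pair_config.stride

    def test_never_more_instances_than_identities(self, skeleton, pair_config, rng):
        heat = rng.uniform(0, 1, size=(5, 12, 12))
        locref = np.zeros((10, 12, 12))
        labels = rng.integers(0, 3, size=(12, 12))
        imap = build_identity_map(labels, np.zeros((2, 12, 12)), pair_config)
        per_id, _ = decode_social({"heatmap": heat, "locref": locref}, imap, pair_config)
        assert len(per_id) <= pair_config.n_identities
        for dets in per_id.values():
            assert len(dets) <= skeleton.n_keypoints

    def test_background_window_peak_is_excluded_and_counted(self, pair_config):
        heat = np.zeros((1, 8, 8))
        heat[0, 4, 4] = 1.0
        imap = build_identity_map(
            np.zeros((8, 8), dtype=np.int64), np.zeros((2, 8, 8)), pair_config
        )
        per_id, diag = decode_social(
            {"heatmap": heat, "locref": np.zeros((2, 8, 8))}, imap, pair_config
        )
        assert per_id == {}
        assert diag["unmatched_peaks"] == 1


class TestTemporalCorrection:
    def _stationary_track(self, F=40, sep=200.0):
        kp = np.zeros((F, 2, 5, 2))
        kp[:, 1] += sep
        conf = np.ones((F, 2, 5))
        ids = np.tile([1, 2], (F, 1))
        ctr = kp[:, :, 1, :].copy()
        return adpt.PoseTrack(kp, conf, ids, ctr)

    def test_clean_track_is_fixed_point(self, pair_config):
        track = self._stationary_track()
        fixed = temporal_identity_correction(track, pair_config)
        assert np.array_equal(fixed.identities, track.identities)
        assert np.array_equal(fixed.keypoints, track.keypoints)

    def test_single_frame_swap_removed_and_change_rate_zero(self, pair_config):
        track = self._stationary_track()
        track.identities[17] = [2, 1]
        before, _ = adpt.change_rate(adpt.centers_by_identity(track, 2), 75.0)
        assert before > 0
        fixed = temporal_identity_correction(track, pair_config)
        after, _ = adpt.change_rate(adpt.centers_by_identity(fixed, 2), 75.0)
        assert after == 0.0
        assert np.array_equal(fixed.identities, self._stationary_track().identities)

    def test_alternating_permutation_converges_to_frame_one(self, pair_config):
        track = self._stationary_track()
        track.identities[1::2] = [2, 1]
        fixed = temporal_identity_correction(track, pair_config)
        assert np.all(fixed.identities == [1, 2])

    def test_only_identities_change_and_idempotent(self, pair_config):
        track = self._stationary_track()
        track.identities[10] = [2, 1]
        fixed = temporal_identity_correction(track, pair_config)
        assert np.array_equal(fixed.keypoints, track.keypoints)
        assert np.array_equal(fixed.confidences, track.confidences)
        twice = temporal_identity_correction(fixed, pair_config)
        assert np.array_equal(twice.identities, fixed.identities)

    def test_empty_frames_pass_through(self, pair_config):
        track = self._stationary_track(F=10)
        track.centers[4] = np.nan
        track.identities[4] = 0
        fixed = temporal_identity_correction(track, pair_config)
        assert fixed.n_frames == 10
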