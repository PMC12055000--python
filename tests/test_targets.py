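import numpy as np
import pytest

import adpt
from adpt.targets import make_baf, make_heatmap_and_locref, make_lrss, map_shape

from conftest import random_keypoint_frame
from oracles import oracle_segment_cells


def _single_kp_frame(x, y, skeleton, size=64):
    kp = np.full((skeleton.n_keypoints, 2), np.nan)
    vis = np.zeros(skeleton.n_keypoints, dtype=bool)
    kp[0] = (x, y)
    vis[0] = True
    img = np.zeros((size, size, 3), dtype=np.uint8)
    return adpt.LabeledFrame(img, [adpt.Instance(1, kp, vis)])


class TestHeatmapLocref:
    def test_keypoint_on_cell_gets_peak_one_and_zero_locref(self, skeleton, config):
        frame = _single_kp_frame(24.0, 32.0, skeleton)  # cell (4, 3) exactly
        tm = make_heatmap_and_locref(frame, skeleton, config)
        assert tm.heatmaps[0, 4, 3] == 1.0
        assert tm.locref[0, 4, 3] == 0.0 and tm.locref[1, 4, 3] == 0.0
        assert tm.locref_mask[0, 4, 3] == 1.0

    def test_gaussian_value_at_distance_three(self, skeleton):
        cfg = adpt.Config(sigma=3.0)
        frame = _single_kp_frame(24.0, 32.0, skeleton)
        tm = make_heatmap_and_locref(frame, skeleton, cfg)
        # cell (4, 6) is 3 cells from the peak cell (4, 3)
        assert tm.heatmaps[0, 4, 6] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_no_visible_keypoints_gives_empty_targets(self, skeleton, config):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        kp = np.full((skeleton.n_keypoints, 2), np.nan)
        frame = adpt.LabeledFrame(
            img, [adpt.Instance(1, kp, np.zeros(skeleton.n_keypoints, dtype=bool))]
        )
        tm = make_heatmap_and_locref(frame, skeleton, config)
        assert not tm.heatmaps.any()
        assert not tm.locref_mask.any()

    def test_peak_cell_is_argmax_for_off_grid_keypoints(self, skeleton, config, rng):
        for _ in range(50):
            x, y = rng.uniform(4, 59, size=2)
            tm = make_heatmap_and_locref(_single_kp_frame(x, y, skeleton), skeleton, config)
            r, c = np.unravel_index(np.argmax(tm.heatmaps[0]), tm.heatmaps[0].shape)
            assert (r, c) == (round(y / 8), round(x / 8))
            assert tm.heatmaps[0, r, c] == 1.0


class TestLRSS:
    def test_zero_instances_gives_zero_map(self, skeleton, config):
        frame = adpt.LabeledFrame(np.zeros((64, 64, 3), dtype=np.uint8), [])
        assert not make_lrss(frame, skeleton, config).any()

    def test_horizontal_edge_spanning_five_cells_thickness_one(self, config):
        sk = adpt.Skeleton(("a", "b"), ((0, 1),), 0)
        kp = np.array([[16.0, 24.0], [48.0, 24.0]])  # cells (3,2) to (3,6)
        frame = adpt.LabeledFrame(
            np.zeros((64, 64, 3), dtype=np.uint8),
            [adpt.Instance(1, kp, np.ones(2, dtype=bool))],
        )
        lrss = make_lrss(frame, sk, config.replace(limb_thickness=1.0))
        nz = np.argwhere(lrss)
        assert len(nz) == 5
        assert set(map(tuple, nz)) == {(3, c) for c in range(2, 7)}
        assert np.all(lrss[lrss != 0] == 1)

    def test_matches_brute_force_rasterization(self, config, rng):
        sk = adpt.Skeleton(("a", "b"), ((0, 1),), 0)
        for _ in range(20):
            kp = rng.uniform(2, 61, size=(2, 2))
            frame = adpt.LabeledFrame(
                np.zeros((64, 64, 3), dtype=np.uint8),
                [adpt.Instance(1, kp, np.ones(2, dtype=bool))],
            )
            lrss = make_lrss(frame, sk, config)
            expected = oracle_segment_cells(
                (8, 8), kp[0] / 8, kp[1] / 8, config.limb_thickness / 2
            )
            assert set(map(tuple, np.argwhere(lrss))) == expected

    def test_identity_alphabet_for_ten_identity_task(self, skeleton):
        """Ten identities plus background give labels {0..10}, matching an
        11-channel segmentation head."""
        cfg = adpt.Config(n_identities=10)
        img = np.zeros((200, 200, 3), dtype=np.uint8)
        instances = []
        rng = np.random.default_rng(0)
        for ident in range(1, 11):
            base = rng.uniform(20, 180, size=2)
            kp = base + rng.uniform(-6, 6, size=(skeleton.n_keypoints, 2))
            instances.append(
                adpt.Instance(ident, kp, np.ones(skeleton.n_keypoints, dtype=bool))
            )
        frame = adpt.LabeledFrame(img, instances)
        lrss = make_lrss(frame, skeleton, cfg, identity_aware=True)
        assert set(np.unique(lrss)) <= set(range(11))
        assert lrss.max() == 10

    def test_identity_exceeding_channel_count_is_hard_error(self, skeleton, config):
        frame = random_keypoint_frame(np.random.default_rng(0), skeleton)
        frame.instances[0].identity = 5
        with pytest.raises(ValueError, match="n_identities"):
            make_lrss(frame, skeleton, config.replace(n_identities=2))

    def test_first_instance_wins_on_overlap(self, config):
        sk = adpt.Skeleton(("a", "b"), ((0, 1),), 0)
        kp = np.array([[8.0, 24.0], [56.0, 24.0]])
        mk = lambda ident: adpt.Instance(ident, kp.copy(), np.ones(2, dtype=bool))
        frame = adpt.LabeledFrame(
            np.zeros((64, 64, 3), dtype=np.uint8), [mk(1), mk(2)]
        )
        lrss = make_lrss(frame, sk, config.replace(n_identities=2))
        assert np.all(lrss[lrss != 0] == 1)


class TestBAF:
    def test_center_cell_vector_is_zero(self, skeleton, pair_config, rng):
        frame = random_keypoint_frame(rng, skeleton)
        ci = skeleton.center_index
        frame.instances[0].keypoints[ci] = (32.0, 32.0)  # cell (4, 4)
        baf = make_baf(frame, skeleton, pair_config)
        assert baf[0, 4, 4] == 0.0 and baf[1, 4, 4] == 0.0

    def test_inverting_baf_recovers_center_exactly(self, skeleton, pair_config):
        """p - BAF(p) equals the instance center on every body cell."""
        frame, _ = adpt.generate_scene(
            adpt.SceneSpec(image_size=(96, 96), n_animals=2, seed=11), return_masks=True
        )
        lrss = make_lrss(frame, skeleton, pair_config, identity_aware=True)
        baf = make_baf(frame, skeleton, pair_config)
        centers = {
            inst.identity: inst.keypoints[skeleton.center_index] / pair_config.stride
            for inst in frame.instances
        }
        for r, c in np.argwhere(lrss != 0):
            center = centers[lrss[r, c]]
            assert c - baf[0, r, c] == pytest.approx(center[0], abs=1e-9)
            assert r - baf[1, r, c] == pytest.approx(center[1], abs=1e-9)

    def test_baf_support_equals_lrss_support(self, skeleton, pair_config):
        frame = adpt.generate_scene(
            adpt.SceneSpec(image_size=(96, 96), n_animals=2, seed=5)
        )
        lrss = make_lrss(frame, skeleton, pair_config, identity_aware=True)
        baf = make_baf(frame, skeleton, pair_config)
        support = (baf != 0).any(axis=0)
        # nonzero vectors only on body cells
        assert np.all(lrss[support] != 0)
        # every body cell carries a vector, except a cell exactly on its
        # instance's (grid-aligned) center where the vector is legitimately 0
        centers = {
            inst.identity: inst.keypoints[skeleton.center_index] / pair_config.stride
            for inst in frame.instances
        }
        for r, c in np.argwhere(lrss != 0):
            if not support[r, c]:
                cx, cy = centers[lrss[r, c]]
                assert np.hypot(c - cx, r - cy) < 1e-9

    def test_missing_center_contributes_nothing(self, skeleton, pair_config, rng):
        frame = random_keypoint_frame(rng, skeleton)
        frame.instances[0].visibility[skeleton.center_index] = False
        baf = make_baf(frame, skeleton, pair_config)
        assert not baf.any()
        assert make_baf.last_missing_centers == 1


def test_debug_dump_writes_multipage_stack(tmp_path, skeleton, config):
    from adpt.targets import dump_targets, encode_frame

    frame = adpt.generate_scene(adpt.SceneSpec(seed=2))
    _, tm = encode_frame(frame, skeleton, config, identity_aware=True, with_baf=True)
    out = tmp_path / "targets.tiff"
    dump_targets(tm, out)
    import imageio.v2 as imageio

    pages = imageio.mimread(out)
    assert len(pages) == 5 + 10 + 5 + 1 + 2  # heat + locref + mask + lrss + baf
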