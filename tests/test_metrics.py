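import numpy as np
import pytest

import adpt
from adpt.metrics import (
    MAP_THRESHOLDS,
    OKSParams,
    change_rate,
    drift_fraction,
    drift_report,
    map_score,
    miss_fraction,
    oks,
    pck,
    rmse,
)

from oracles import (
    oracle_change_rate,
    oracle_drift,
    oracle_map,
    oracle_miss,
    oracle_oks,
    oracle_pck,
    oracle_rmse,
)


class TestDrift:
    def test_constant_trajectory_has_zero_drift(self):
        traj = np.tile([[3.0, 4.0]], (10, 1, 1))
        assert np.all(drift_fraction(traj, 50.0) == 0.0)

    def test_single_jump_counts_once_over_F(self):
        traj = np.zeros((100, 1, 2))
        traj[40:, 0, 0] = 60.0  # one persistent 60 px step
        assert drift_fraction(traj, 50.0)[0] == pytest.approx(1 / 100)

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            F = int(rng.integers(2, 50))
            K = int(rng.integers(1, 5))
            traj = rng.uniform(0, 200, size=(F, K, 2))
            alpha = float(rng.uniform(5, 150))
            assert np.allclose(drift_fraction(traj, alpha), oracle_drift(traj, alpha))

    def test_count_stable_flag_flips_inequality(self, rng):
        traj = rng.uniform(0, 100, size=(20, 2, 2))
        drift = drift_fraction(traj, 30.0)
        stable = drift_fraction(traj, 30.0, count_stable=True)
        assert np.allclose(drift + stable, (20 - 1) / 20)

    def test_short_track_is_hard_error(self):
        with pytest.raises(ValueError):
            drift_fraction(np.zeros((1, 1, 2)), 50.0)

    def test_reversal_invariance(self, rng):
        traj = rng.uniform(0, 100, size=(30, 3, 2))
        assert np.allclose(drift_fraction(traj, 40.0), drift_fraction(traj[::-1], 40.0))


class TestMiss:
    def test_full_confidence_never_misses(self):
        assert np.all(miss_fraction(np.ones((10, 3))) == 0.0)

    def test_cutoff_is_inclusive(self):
        conf = np.array([[0.2], [0.9]])
        assert miss_fraction(conf, 0.2)[0] == pytest.approx(0.5)

    def test_mixed_confidences(self):
        conf = np.concatenate([np.full((3, 1), 0.1), np.full((7, 1), 0.9)])
        assert miss_fraction(conf, 0.2)[0] == pytest.approx(0.3)

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            conf = rng.uniform(0, 1, size=(int(rng.integers(1, 50)), 4))
            cutoff = float(rng.uniform(0.05, 0.8))
            assert np.allclose(miss_fraction(conf, cutoff), oracle_miss(conf, cutoff))


class TestChangeRate:
    def test_stationary_centers(self):
        centers = np.tile([[0.0, 0.0], [100.0, 100.0]], (10, 1, 1)).reshape(10, 2, 2)
        mean, per = change_rate(centers, 75.0)
        assert mean == 0.0

    def test_swap_between_distant_animals_counts_for_both(self):
        F = 50
        centers = np.zeros((F, 2, 2))
        centers[:, 1, 0] = 200.0
        centers[25, [0, 1]] = centers[25, [1, 0]]  # one-frame identity swap
        mean, per = change_rate(centers, 75.0)
        assert np.allclose(per, 2 / F)  # jump out and back for each identity

    def test_matches_brute_force_with_gaps(self, rng):
        for _ in range(200):
            F = int(rng.integers(2, 50))
            centers = rng.uniform(0, 300, size=(F, 2, 2))
            centers[rng.uniform(size=F) < 0.1] = np.nan
            alpha = float(rng.uniform(20, 150))
            got = change_rate(centers, alpha)
            want = oracle_change_rate(centers, alpha)
            assert got[0] == pytest.approx(want[0])
            assert np.allclose(got[1], want[1])


class TestPCK:
    def test_perfect_prediction_scores_one(self, skeleton, rng):
        gt = rng.uniform(10, 90, size=(4, 5, 2))
        assert pck(gt, gt, skeleton) == 1.0

    def test_error_beyond_threshold_scores_zero(self):
        sk = adpt.Skeleton(("a", "b"), ((0, 1),), 0, pck_reference="edge:0-1")
        gt = np.array([[[0.0, 0.0], [10.0, 0.0]]])  # L = 10
        pred = gt + np.array([2.0, 0.0])  # d = 0.2 L > 0.15 L
        assert pck(pred, gt, sk) == 0.0

    def test_matches_brute_force(self, skeleton, rng):
        for _ in range(100):
            N = int(rng.integers(1, 10))
            gt = rng.uniform(0, 100, size=(N, 5, 2))
            pred = gt + rng.normal(0, 3, size=gt.shape)
            vis = rng.uniform(size=(N, 5)) > 0.2
            vis[:, 0] = True
            pts = np.where(vis[..., None], gt, np.nan)
            L = np.sqrt(
                (np.nanmax(pts[..., 0], axis=1) - np.nanmin(pts[..., 0], axis=1))
                * (np.nanmax(pts[..., 1], axis=1) - np.nanmin(pts[..., 1], axis=1))
            )
            got = pck(pred, gt, skeleton, visibility=vis)
            assert got == pytest.approx(oracle_pck(pred, gt, vis, L, 0.15))

    def test_no_visible_keypoints_is_nan(self, skeleton):
        gt = np.zeros((1, 5, 2))
        assert np.isnan(pck(gt, gt, skeleton, visibility=np.zeros((1, 5), dtype=bool)))


class TestOKS:
    def test_perfect_prediction(self):
        gt = np.array([[3.0, 4.0], [5.0, 6.0]])
        assert oks(gt, gt, OKSParams(area=100.0)) == 1.0

    def test_closed_form_inversion(self):
        """d = sqrt(area) * 2s makes the exponent -1/2 exactly."""
        area, s = 400.0, 0.025
        d = np.sqrt(area) * 2 * s
        gt = np.array([[10.0, 10.0]])
        pred = gt + [d, 0.0]
        assert oks(pred, gt, OKSParams(area=area, s=s)) == pytest.approx(np.exp(-0.5))

    def test_zero_visible_is_hard_error(self):
        with pytest.raises(ValueError):
            oks(
                np.zeros((2, 2)),
                np.zeros((2, 2)),
                OKSParams(area=10.0, visibility=np.zeros(2, dtype=bool)),
            )

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            K = int(rng.integers(1, 10))
            gt = rng.uniform(0, 100, size=(K, 2))
            pred = gt + rng.normal(0, 5, size=(K, 2))
            vis = rng.uniform(size=K) > 0.3
            vis[0] = True
            area = float(rng.uniform(50, 2000))
            got = oks(pred, gt, OKSParams(area=area, visibility=vis))
            assert got == pytest.approx(oracle_oks(pred, gt, vis, area, 0.025))

    def test_coco_mode_differs(self):
        gt = np.array([[0.0, 0.0]])
        pred = np.array([[3.0, 0.0]])
        p = OKSParams(area=100.0)
        assert oks(pred, gt, p, coco=True) < oks(pred, gt, p)


class TestMAP:
    def test_all_perfect(self):
        m, ap = map_score([1.0, 1.0, 1.0])
        assert m == 1.0 and all(v == 1.0 for v in ap.values())

    def test_worked_example(self):
        # strict inequality: AP@0.6 excludes the OKS = 0.6 instance and
        # AP@0.8 excludes the 0.8 one, so the ten APs are
        # 1, 1, .5, .5, .5, .5, 0, 0, 0, 0 -> mean 0.40
        m, ap = map_score([0.6, 0.8])
        assert ap[0.5] == 1.0 and ap[0.7] == 0.5 and ap[0.85] == 0.0
        assert m == pytest.approx(0.40)

    def test_threshold_grid(self):
        assert MAP_THRESHOLDS == tuple(np.round(np.arange(0.5, 0.951, 0.05), 2))

    def test_strict_inequality_at_threshold(self):
        _, ap = map_score([0.5])
        assert ap[0.5] == 0.0  # OKS == alpha does not count

    def test_non_increasing_in_threshold_and_matches_oracle(self, rng):
        for _ in range(200):
            vals = rng.uniform(0, 1, size=int(rng.integers(1, 50)))
            m, ap = map_score(vals)
            om, oap = oracle_map(list(vals))
            assert m == pytest.approx(om)
            curve = [ap[t] for t in sorted(ap)]
            assert all(a >= b for a, b in zip(curve, curve[1:]))

    def test_empty_list_is_hard_error(self):
        with pytest.raises(ValueError):
            map_score([])


class TestRMSE:
    def test_identical_is_zero(self):
        gt = np.array([[1.0, 2.0]])
        assert rmse(gt, gt) == 0.0

    def test_three_four_five_triangle(self):
        assert rmse(np.array([[3.0, 4.0]]), np.array([[0.0, 0.0]])) == pytest.approx(5.0)

    @pytest.mark.parametrize("cutoff", [0.2, 0.6])
    def test_confidence_cutoffs_match_oracle(self, rng, cutoff):
        for _ in range(100):
            K = int(rng.integers(1, 50))
            gt = rng.uniform(0, 100, size=(K, 2))
            pred = gt + rng.normal(0, 4, size=(K, 2))
            conf = rng.uniform(0, 1, size=K)
            got = rmse(pred, gt, conf, cutoff)
            want = oracle_rmse(pred, gt, conf, cutoff)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want)


class TestDriftReport:
    def test_report_on_synthetic_video(self, skeleton, pair_config):
        spec = adpt.SceneSpec(
            image_size=(160, 160), n_animals=2, seed=4, min_separation=100.0,
            n_swap_events=1,
        )
        frames, events = adpt.generate_video(spec, 60)
        track = adpt.apply_events(adpt.gt_track(frames), events)
        report = drift_report(track, skeleton, pair_config)
        assert 0.0 <= report.overall_drift <= 1.0
        assert report.overall_miss == 0.0
        assert report.change_rate > 0.0  # the injected swap is visible
        d = report.to_dict()
        assert set(d["per_keypoint"]) == set(skeleton.names)
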