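"""Epipolar pose chain: Euler angles, F/E estimation, pose recovery, triangulation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from voxrecon import pose as pg
from voxrecon.synthetic_data import default_intrinsics

RNG = np.random.default_rng(21)


def make_two_view(R, t, n=60, seed=0, K=None, depth=5.0):
    """Project random 3-D points into two views; returns (MatchSet, K, X)."""
    rng = np.random.default_rng(seed)
    K = default_intrinsics(200, 200) if K is None else K
    X = rng.uniform(-1, 1, size=(n, 3)) + np.array([0.0, 0.0, depth])

    def project(Rc, tc):
        pc = X @ Rc.T + tc
        return np.stack([K[0, 0] * pc[:, 0] / pc[:, 2] + K[0, 2],
                         K[1, 1] * pc[:, 1] / pc[:, 2] + K[1, 2]], axis=1)

    m = pg.MatchSet.from_correspondences(project(np.eye(3), np.zeros(3)), project(R, t))
    return m, K, X


class TestEuler:
    def test_identity_and_single_axis(self):
        e = pg.rotation_to_euler(np.eye(3))
        assert e.as_array() == pytest.approx([0.0, 0.0, 0.0])
        e = pg.rotation_to_euler(pg.euler_to_rotation(np.pi / 6, 0, 0))
        assert e.as_array() == pytest.approx([np.pi / 6, 0.0, 0.0], abs=1e-12)

    def test_round_trip_random_angles(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = rng.uniform(-np.pi, np.pi)
            b = rng.uniform(-np.pi / 2 + 0.05, np.pi / 2 - 0.05)
            g = rng.uniform(-np.pi, np.pi)
            e = pg.rotation_to_euler(pg.euler_to_rotation(a, b, g))
            assert np.allclose(e.as_array(), [a, b, g], atol=1e-9)

    def test_agrees_with_scipy_rotation(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            R = Rotation.random(random_state=rng).as_matrix()
            ours = pg.rotation_to_euler(R)
            if ours.gimbal_lock:
                continue
            ref = Rotation.from_matrix(R).as_euler("ZYX")  # intrinsic z-y-x
            assert np.allclose(ours.as_array(), ref, atol=1e-9)

    def test_gimbal_lock_flagged_and_consistent(self):
        R = pg.euler_to_rotation(0.4, np.pi / 2, 0.3)
        e = pg.rotation_to_euler(R)
        assert e.gimbal_lock and e.gamma == 0.0
        assert np.allclose(pg.euler_to_rotation(*e.as_array()), R, atol=1e-9)

    def test_non_rotation_rejected(self):
        with pytest.raises(ValueError):
            pg.rotation_to_euler(np.eye(3) * 2.0)

    def test_wrap_angle(self):
        a, b = np.deg2rad(179.0), np.deg2rad(-179.0)
        assert np.abs(pg.wrap_angle(a - b)) == pytest.approx(np.deg2rad(2.0))
        assert pg.wrap_angle(np.pi) == pytest.approx(np.pi)  # half-open interval


class TestMatching:
    def test_identity_matching_with_zero_distances(self):
        desc = RNG.random((20, 16))
        kp = RNG.random((20, 2)) * 100
        ms = pg.match_descriptors(kp, desc, kp, desc, "euclidean")
        assert len(ms) == 20
        assert all(i == j and d == 0.0 for i, j, d in ms.pairs)

    def test_empty_side_gives_empty_matchset(self):
        ms = pg.match_descriptors(np.zeros((0, 2)), np.zeros((0, 8)),
                                  RNG.random((5, 2)), RNG.random((5, 8)), "euclidean")
        assert len(ms) == 0

    def test_matches_agree_with_brute_force_cross_check(self):
        a = RNG.random((40, 8))
        b = RNG.random((30, 8))
        ms = pg.match_descriptors(RNG.random((40, 2)), a, RNG.random((30, 2)), b,
                                  "euclidean")
        d = np.linalg.norm(a[:, None] - b[None], axis=2)
        expected = set()
        for i in range(40):
            j = int(d[i].argmin())
            if int(d[:, j].argmin()) == i:
                expected.add((i, j))
        assert {(i, j) for i, j, _ in ms.pairs} == expected
        dists = [p[2] for p in ms.pairs]
        assert dists == sorted(dists)

    def test_hamming_metric_for_binary_descriptors(self):
        a = (RNG.random((10, 32)) > 0.5).astype(np.uint8)
        b = a.copy()
        b[0, :4] ^= 1  # 4-bit flip
        ms = pg.match_descriptors(RNG.random((10, 2)), a, RNG.random((10, 2)), b,
                                  "hamming")
        d0 = [d for i, j, d in ms.pairs if i == 0]
        assert d0 == [4.0]


class TestDetectors:
    def test_constant_image_yields_no_keypoints(self):
        img = np.full((64, 64, 3), 0.5)
        for kind in pg.AVAILABLE_KINDS:
            kp, desc, _ = pg.detect_and_describe(img, kind)
            assert len(kp) == 0

    def test_unavailable_backends_raise_informatively(self):
        img = RNG.random((32, 32, 3))
        for kind in ("brisk", "akaze"):
            with pytest.raises(pg.BackendUnavailableError):
                pg.detect_and_describe(img, kind)
        with pytest.raises(ValueError):
            pg.detect_and_describe(img, "surf")

    def test_detection_is_deterministic(self, two_view_scene):
        kp1, d1, _ = pg.detect_and_describe(two_view_scene["img_a"], "sift")
        kp2, d2, _ = pg.detect_and_describe(two_view_scene["img_a"], "sift")
        assert np.array_equal(kp1, kp2) and np.array_equal(d1, d2)
        assert len(kp1) >= 8


class TestFundamentalEssential:
    def test_noiseless_epipolar_residuals(self):
        R = pg.euler_to_rotation(0.1, -0.15, 0.05)
        t = np.array([0.5, 0.2, -0.1])
        m, K, _ = make_two_view(R, t / np.linalg.norm(t))
        res = pg.estimate_fundamental(m, seed=0)
        assert res.inliers.all() and not res.degenerate
        pa = np.column_stack([m.points_a, np.ones(len(m))])
        pb = np.column_stack([m.points_b, np.ones(len(m))])
        residual = np.abs(np.einsum("ij,ij->i", pb, pa @ res.F.T))
        assert residual.max() < 1e-8  # F is unit Frobenius norm
        assert abs(np.linalg.det(res.F)) < 1e-10
        assert np.isclose(np.linalg.norm(res.F), 1.0)

    def test_ransac_rejects_outliers_deterministically(self):
        R = pg.euler_to_rotation(0.2, 0.1, 0.0)
        t = np.array([1.0, 0.0, 0.2])
        m, K, _ = make_two_view(R, t / np.linalg.norm(t), n=80)
        rng = np.random.default_rng(5)
        bad = rng.choice(80, size=15, replace=False)
        pts_b = m.points_b.copy()
        pts_b[bad] += rng.uniform(20, 60, size=(15, 2))
        m2 = pg.MatchSet.from_correspondences(m.points_a, pts_b)
        r1 = pg.estimate_fundamental(m2, seed=7)
        r2 = pg.estimate_fundamental(m2, seed=7)
        assert np.array_equal(r1.inliers, r2.inliers)
        assert not r1.inliers[bad].any()
        assert r1.inliers.sum() >= 60

    def test_too_few_matches_raise(self):
        m = pg.MatchSet.from_correspondences(RNG.random((5, 2)), RNG.random((5, 2)))
        with pytest.raises(ValueError):
            pg.estimate_fundamental(m)

    def test_essential_matrix_properties(self):
        R = pg.euler_to_rotation(0.0, 0.18, 0.0)
        t = np.array([0.8, 0.1, 0.0])
        m, K, _ = make_two_view(R, t / np.linalg.norm(t))
        F = pg.estimate_fundamental(m, seed=0).F
        E = pg.essential_from_fundamental(F, K)
        s = np.linalg.svd(E, compute_uv=False)
        assert abs(s[0] - s[1]) < 1e-8 * s[0]
        assert s[2] < 1e-8 * s[0]
        # K = I leaves F unchanged up to manifold projection
        E_id = pg.essential_from_fundamental(F, np.eye(3))
        u, sv, vt = np.linalg.svd(F)
        proj = u @ np.diag([(sv[0] + sv[1]) / 2] * 2 + [0.0]) @ vt
        assert np.allclose(E_id, proj, atol=1e-12)
        with pytest.raises(ValueError):
            pg.essential_from_fundamental(F, np.zeros((3, 3)))


class TestPoseRecovery:
    def test_ten_degree_rotation_recovered_exactly(self):
        R_true = pg.euler_to_rotation(0.0, np.deg2rad(10.0), 0.0)  # about y
        t_true = np.array([0.6, 0.1, 0.15])
        t_true = t_true / np.linalg.norm(t_true)
        m, K, _ = make_two_view(R_true, t_true, seed=3)
        res = pg.estimate_fundamental(m, seed=0)
        E = pg.essential_from_fundamental(res.F, K)
        est = pg.recover_pose(E, m, K, inliers=res.inliers)
        geodesic = np.arccos(np.clip((np.trace(est.R.T @ R_true) - 1) / 2, -1, 1))
        assert geodesic < 1e-6
        assert np.linalg.norm(est.t) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(est.t, t_true, atol=1e-6)

    def test_pure_rotation_flagged_degenerate(self):
        R_true = pg.euler_to_rotation(0.0, np.deg2rad(15.0), 0.0)
        m, K, _ = make_two_view(R_true, np.zeros(3), seed=4)
        res = pg.estimate_fundamental(m, seed=0)
        E = pg.essential_from_fundamental(res.F, K)
        with pytest.raises(pg.DegenerateGeometryError):
            pg.recover_pose(E, m, K, inliers=res.inliers)


class TestTriangulation:
    def _chain(self, seed=6):
        R_true = pg.euler_to_rotation(0.12, -0.08, 0.05)
        t_true = np.array([0.7, -0.2, 0.1])
        t_true /= np.linalg.norm(t_true)
        m, K, X = make_two_view(R_true, t_true, seed=seed)
        res = pg.estimate_fundamental(m, seed=0)
        E = pg.essential_from_fundamental(res.F, K)
        est = pg.recover_pose(E, m, K, inliers=res.inliers)
        return m, K, X, est

    def test_reprojection_error_below_tolerance(self):
        m, K, X, est = self._chain()
        cloud = pg.triangulate(m, K, est)
        pc = cloud  # first-camera frame
        proj = np.stack([K[0, 0] * pc[:, 0] / pc[:, 2] + K[0, 2],
                         K[1, 1] * pc[:, 1] / pc[:, 2] + K[1, 2]], axis=1)
        assert np.abs(proj - m.points_a[est.inliers]).max() < 1e-6

    def test_cloud_matches_truth_up_to_similarity(self):
        m, K, X, est = self._chain()
        cloud = pg.triangulate(m, K, est)
        assert len(cloud) == len(X)
        # similarity (Procrustes with scale) alignment residual ~ 0
        mu_a, mu_b = cloud.mean(axis=0), X.mean(axis=0)
        A, B = cloud - mu_a, X - mu_b
        u, s, vt = np.linalg.svd(A.T @ B)
        d = np.sign(np.linalg.det(u @ vt))
        Rp = u @ np.diag([1, 1, d]) @ vt
        scale = (s * [1, 1, d]).sum() / (A**2).sum()
        resid = np.abs(scale * A @ Rp - B).max()
        assert resid < 1e-6

    def test_single_pair_triangulates_single_point(self):
        R_true = pg.euler_to_rotation(0.0, 0.1, 0.0)
        t_true = np.array([1.0, 0.0, 0.0])
        m, K, X = make_two_view(R_true, t_true, n=1, seed=8)
        pose = pg.PoseEstimate(R_true, t_true, np.ones(1, dtype=bool))
        cloud = pg.triangulate(m, K, pose)
        assert cloud.shape == (1, 3)
        assert np.allclose(cloud[0], X[0], atol=1e-6)


class TestPoseErrors:
    def test_zero_for_equal_lists(self):
        e = [pg.EulerAngles(0.1, 0.2, -0.3)] * 3
        assert pg.pose_error_metrics(e, list(e)) == (0.0, 0.0, 0.0)

    def test_single_right_angle(self):
        res = pg.pose_error_metrics([np.array([0.0])], [np.array([np.pi / 2])])
        assert res[0] == pytest.approx(np.pi / 2)
        assert res[1] == pytest.approx(np.pi**2 / 4)
        assert res[2] == pytest.approx(np.pi / 2)

    def test_wrapping_across_pi(self):
        res = pg.pose_error_metrics([np.array([np.deg2rad(179.0)])],
                                    [np.array([np.deg2rad(-179.0)])])
        assert res[0] == pytest.approx(np.deg2rad(2.0), abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pg.pose_error_metrics([np.zeros(3)], [np.zeros(3), np.zeros(3)])


def test_end_to_end_detector_chain_on_textured_scene(two_view_scene):
    """Full chain with detector-found correspondences recovers the true pose."""
    sc = two_view_scene
    kp_a, d_a, metric = pg.detect_and_describe(sc["img_a"], "sift")
    kp_b, d_b, _ = pg.detect_and_describe(sc["img_b"], "sift")
    m = pg.match_descriptors(kp_a, d_a, kp_b, d_b, metric, "sift")
    res = pg.estimate_fundamental(m, seed=0)
    E = pg.essential_from_fundamental(res.F, sc["K"])
    est = pg.recover_pose(E, m, sc["K"], inliers=res.inliers)
    mae_angle, _, _ = pg.pose_error_metrics(
        [pg.rotation_to_euler(est.R)], [pg.rotation_to_euler(sc["R"])]
    )
    assert mae_angle <= 0.05
    # declared inliers respect the Sampson threshold by construction
    from voxrecon.pose import _sampson_distance

    d = _sampson_distance(res.F, m.points_a, m.points_b)
    assert np.all(d[res.inliers] < 1.0)
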