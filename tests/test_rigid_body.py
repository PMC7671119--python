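"""Rigid-body pose fitting, precision metric, gap filling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from vromm.cameras import MarkerTrajectory3D
from vromm.rigid_body import (
    RigidBodyDef,
    canonical_body_frame,
    fill_gaps,
    fit_body_plane,
    fit_rigid_pose,
    fit_rigid_poses,
    pairwise_distance_precision,
)

REF4 = np.array(
    [[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 8.0, 0.0], [2.0, 3.0, 6.0]]
)
BODY = RigidBodyDef("b", ["m1", "m2", "m3", "m4"], REF4)


def brute_force_pose(ref, obs):
    """Independent oracle: direct numerical minimization over rotation+translation."""

    def cost(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        return np.sum((ref @ R.T + x[3:] - obs) ** 2)

    best = None
    for x0 in ([0, 0, 0, 0, 0, 0], [0.5, -0.3, 0.2, 1, 1, 1], [-1, 1, 0.5, 0, 0, 0]):
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    return Rotation.from_rotvec(best.x[:3]).as_matrix(), best.x[3:]


def rotation_angle(Ra, Rb):
    """Geodesic angle (rad) between two rotations."""
    return Rotation.from_matrix(Ra.T @ Rb).magnitude()


class TestPoseFit:
    def test_reference_observed_gives_identity(self):
        R, t, res, status = fit_rigid_pose(BODY, REF4)
        assert status == "ok"
        assert np.allclose(R, np.eye(3), atol=1e-12)
        assert np.allclose(t, 0, atol=1e-12)
        assert res < 1e-12

    def test_constructed_transform_recovered(self):
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        obs = REF4 @ Rz.T + np.array([1.0, 2.0, 3.0])
        R, t, res, status = fit_rigid_pose(BODY, obs)
        assert status == "ok"
        assert np.allclose(R, Rz, atol=1e-9)
        assert np.allclose(t, [1, 2, 3], atol=1e-9)
        assert res < 1e-9

    def test_reflection_never_returned(self, rng):
        for _ in range(50):
            obs = REF4 + rng.normal(0, 2.0, REF4.shape)
            R, *_ , status = fit_rigid_pose(BODY, obs)
            if status == "ok":
                assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_two_markers_is_missing_frame(self):
        obs = REF4.copy()
        obs[2:] = np.nan
        *_, status = fit_rigid_pose(BODY, obs)
        assert status == "missing"

    def test_collinear_markers_flagged_degenerate(self):
        obs = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
        *_, status = fit_rigid_pose(BODY, obs)
        assert status == "degenerate"

    def test_svd_matches_brute_force_minimizer(self, rng):
        """Oracle equivalence on random noisy 4-marker frames."""
        for _ in range(20):
            R_true = Rotation.random(rng=rng).as_matrix()
            t_true = rng.uniform(-5, 5, 3)
            obs = REF4 @ R_true.T + t_true + rng.normal(0, 0.1, REF4.shape)
            R_svd, t_svd, _, _ = fit_rigid_pose(BODY, obs)
            R_bf, t_bf = brute_force_pose(REF4, obs)
            assert rotation_angle(R_svd, R_bf) < 1e-6
            assert np.max(np.abs(t_svd - t_bf)) < 1e-6

    def test_noise_residual_scale(self, rng):
        """Residual (RMS per-point misfit) under iid noise follows degrees-of-
        freedom counting: 3M noisy coordinates minus 6 pose dof spread over M
        points gives E[RMS^2] = sd^2 * (3M - 6)/M, i.e. sd*sqrt(3 - 6/M)."""
        sd, M = 0.1, 4
        rms = []
        for _ in range(1000):
            obs = REF4 + rng.normal(0, sd, REF4.shape)
            *_, res, status = fit_rigid_pose(BODY, obs)
            rms.append(res**2)
        expected = sd * np.sqrt(3 - 6 / M)
        assert np.sqrt(np.mean(rms)) == pytest.approx(expected, rel=0.05)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        rotvec=st.tuples(*[st.floats(-1.5, 1.5) for _ in range(3)]),
        shift=st.tuples(*[st.floats(-20, 20) for _ in range(3)]),
    )
    def test_equivariance_under_rigid_motion(self, rotvec, shift):
        """Transforming all observations by T yields pose T composed with P."""
        rng = np.random.default_rng(0)
        obs = REF4 @ Rotation.from_euler("xyz", [10, -5, 30], degrees=True).as_matrix().T
        obs = obs + rng.normal(0, 0.05, obs.shape)
        R0, t0, *_ = fit_rigid_pose(BODY, obs)
        T_R = Rotation.from_rotvec(rotvec).as_matrix()
        R1, t1, *_ = fit_rigid_pose(BODY, obs @ T_R.T + np.asarray(shift))
        assert rotation_angle(R1, T_R @ R0) < 1e-9
        assert np.max(np.abs(t1 - (T_R @ t0 + shift))) < 1e-8


class TestBodyPlane:
    REF5 = np.array(
        [[-5, 3, 2], [-20, 3.5, 8], [-35, 3, -4], [-50, 2.5, 6], [-65, 3, 0.0]]
    )
    DEF5 = RigidBodyDef("plane", [f"b{i}" for i in range(5)], REF5)

    def _trajs(self, xyz_per_marker):
        return {f"b{i}": xyz_per_marker[:, i] for i in range(5)}

    def test_requires_five_markers(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_body_plane(BODY, {})

    def test_static_markers_give_constant_pose(self):
        T = 30
        xyz = np.tile(self.REF5, (T, 1, 1))
        pose = fit_body_plane(self.DEF5, self._trajs(xyz))
        for f in range(1, T):
            assert rotation_angle(pose.rotation[0], pose.rotation[f]) < 1e-9
        assert np.ptp(pose.translation, axis=0).max() < 1e-9

    def test_translation_tracked_exactly(self):
        T = 20
        xyz = np.tile(self.REF5, (T, 1, 1))
        xyz[10:] += np.array([5.0, 0, 0])
        pose = fit_body_plane(self.DEF5, self._trajs(xyz))
        jump = pose.translation[15] - pose.translation[5]
        assert np.allclose(jump, [5, 0, 0], atol=1e-9)

    def test_canonical_axes_are_right_handed_orthonormal(self):
        axes, _ = canonical_body_frame(self.REF5)
        assert np.allclose(axes @ axes.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(axes) == pytest.approx(1.0, abs=1e-12)
        # +X points toward the first-listed (rostral-most) marker
        assert axes[0] @ (self.REF5[0] - self.REF5.mean(0)) > 0
        # +Z is the dorsal-most direction orthogonal to X
        assert axes[2] @ np.array([0, 0, 1.0]) > 0

    def test_body_frame_averages_down_noise(self, rng):
        """Marker coords in the fitted frame scatter less than in the world."""
        T, sd = 400, 0.17
        xyz = np.tile(self.REF5, (T, 1, 1)) + rng.normal(0, sd, (T, 5, 3))
        pose = fit_body_plane(self.DEF5, self._trajs(xyz))
        world_sd = xyz[:, 0].std(axis=0, ddof=1).mean()
        axes, c = canonical_body_frame(self.REF5)
        in_frame = np.einsum("fji,fj->fi", pose.rotation, xyz[:, 0] - pose.translation)
        frame_sd = in_frame.std(axis=0, ddof=1).mean()
        assert frame_sd < world_sd


class TestPrecision:
    def test_noiseless_rigid_body_all_pairs_zero(self, clean_pipeline):
        truth = clean_pipeline["truth"]
        report = pairwise_distance_precision(
            clean_pipeline["trajs"], truth.role_map["neurocranium"]
        )
        assert report.n_pairs == 6
        assert np.max(report.pair_sd) < 1e-9
        assert report.mean_sd < 1e-9

    def test_four_markers_give_six_pairs(self, rng):
        trajs = {f"m{i}": rng.normal(size=(50, 3)) for i in range(4)}
        assert pairwise_distance_precision(trajs).n_pairs == 6

    def test_static_pair_gaussian_noise_matches_sqrt2_law(self, rng):
        """Distance SD of a noisy static pair ~ sigma*sqrt(2) (3 MC SE)."""
        sigma, T = 0.1, 10_000
        a = np.array([0.0, 0.0, 0.0]) + rng.normal(0, sigma, (T, 3))
        b = np.array([10.0, 0.0, 0.0]) + rng.normal(0, sigma, (T, 3))
        rep = pairwise_distance_precision({"a": a, "b": b})
        expected = sigma * np.sqrt(2)
        mc_se = expected / np.sqrt(2 * (T - 1))
        assert abs(rep.mean_sd - expected) < 3 * mc_se

    def test_invariant_to_rigid_motion(self, rng):
        xyz = {f"m{i}": np.tile(rng.uniform(-5, 5, 3), (100, 1)) + rng.normal(0, 0.1, (100, 3))
               for i in range(3)}
        base = pairwise_distance_precision(xyz).mean_sd
        R = Rotation.from_euler("xyz", [20, 40, -10], degrees=True).as_matrix()
        moved = {m: v @ R.T + np.array([3.0, -7.0, 2.0]) for m, v in xyz.items()}
        assert pairwise_distance_precision(moved).mean_sd == pytest.approx(base, abs=1e-9)

    def test_filled_frames_excluded(self):
        xyz = np.tile([0.0, 0.0, 0.0], (20, 1))
        a = MarkerTrajectory3D("a", xyz, np.zeros(20))
        bad = xyz.copy()
        bad[5:10] += 99.0  # interpolated values that would inflate the SD
        b = MarkerTrajectory3D(
            "b", bad + [5, 0, 0], np.zeros(20),
            filled=np.isin(np.arange(20), np.arange(5, 10)),
        )
        rep = pairwise_distance_precision({"a": a, "b": b})
        assert rep.mean_sd < 1e-12


class TestFillGaps:
    def _linear_traj(self, gap):
        T = 40
        xyz = np.stack([np.linspace(0, 39, T)] * 3, axis=1)
        xyz[gap] = np.nan
        return MarkerTrajectory3D("m", xyz, np.zeros(T))

    def test_short_gap_filled_on_the_line(self):
        tr = fill_gaps(self._linear_traj(slice(10, 13)), max_gap=5)
        assert not tr.missing[10:13].any()
        assert tr.filled[10:13].all()
        assert np.max(np.abs(tr.xyz[10:13, 0] - [10, 11, 12])) < 1e-9

    def test_long_gap_left_missing(self):
        tr = fill_gaps(self._linear_traj(slice(10, 18)), max_gap=5)
        assert tr.missing[10:18].all()
        assert not tr.filled.any()

    def test_edge_gap_never_extrapolated(self):
        tr = fill_gaps(self._linear_traj(slice(0, 3)), max_gap=5)
        assert tr.missing[:3].all()

    def test_max_gap_zero_is_identity(self):
        src = self._linear_traj(slice(10, 13))
        tr = fill_gaps(src, max_gap=0)
        assert tr is src
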