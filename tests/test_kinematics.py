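"""ACS excursions, JCS elevation, peak-gape detection, trial summary."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from vromm.cameras import MarkerTrajectory3D
from vromm.kinematics import (
    EventTable,
    acs_excursions,
    detect_peak_gape,
    jcs_elevation,
    summarize_trial,
)
from vromm.rigid_body import RigidBodyPose
from vromm.synthetic import raised_cosine


def identity_pose(T, body_id="b"):
    return RigidBodyPose(
        body_id=body_id,
        rotation=np.tile(np.eye(3), (T, 1, 1)),
        translation=np.zeros((T, 3)),
        residual=np.zeros(T),
        missing=np.zeros(T, dtype=bool),
    )


def traj(xyz, marker_id="m"):
    xyz = np.asarray(xyz, dtype=float)
    return MarkerTrajectory3D(marker_id, xyz, np.zeros(len(xyz)))


class TestExcursions:
    def test_sign_convention_caudoventral_is_positive(self):
        """A move of (-2, 0, -3) mm in the body frame reads as retraction 2,
        depression 3."""
        T = 30
        xyz = np.tile([5.0, 1.0, 2.0], (T, 1))
        xyz[20:] += [-2.0, 0.0, -3.0]
        exc = acs_excursions(identity_pose(T), traj(xyz), baseline_window=10)
        assert exc.retraction[25] == pytest.approx(2.0, abs=1e-12)
        assert exc.depression[25] == pytest.approx(3.0, abs=1e-12)

    def test_common_rigid_motion_cancels(self):
        """A marker fixed to the body shows zero excursion while the whole
        fish swims through the tank."""
        T = 50
        R = Rotation.from_euler(
            "z", np.linspace(0, 30, T)[:, None], degrees=True
        ).as_matrix()
        drift = np.linspace(0, 40, T)[:, None] * np.array([1.0, 0.5, 0.2])
        pose = RigidBodyPose("b", R, drift, np.zeros(T), np.zeros(T, dtype=bool))
        q = np.array([4.0, -2.0, 7.0])  # fixed body-frame position
        world = np.einsum("fij,j->fi", R, q) + drift
        exc = acs_excursions(pose, traj(world), baseline_window=10)
        assert np.max(np.abs(exc.retraction)) < 1e-9
        assert np.max(np.abs(exc.depression)) < 1e-9

    def test_baseline_mean_is_zero(self, rng):
        T = 60
        xyz = np.tile([1.0, 2.0, 3.0], (T, 1)) + rng.normal(0, 0.1, (T, 3))
        exc = acs_excursions(identity_pose(T), traj(xyz), baseline_window=20)
        assert np.mean(exc.retraction[:20]) == pytest.approx(0.0, abs=1e-12)
        assert np.mean(exc.depression[:20]) == pytest.approx(0.0, abs=1e-12)

    def test_marker_missing_in_baseline_errors(self):
        T = 30
        xyz = np.tile([1.0, 1.0, 1.0], (T, 1))
        xyz[:20] = np.nan
        with pytest.raises(ValueError, match="baseline"):
            acs_excursions(identity_pose(T), traj(xyz), baseline_window=20)

    def test_generator_closure(self, clean_pipeline):
        """Peak excursions equal the generator amplitudes with zero noise."""
        truth = clean_pipeline["truth"]
        p = truth.params
        for marker, (r_amp, d_amp) in {
            "urohyal": (p.urohyal_retraction_amp, p.urohyal_depression_amp),
            "cleithrum": (p.cleithrum_retraction_amp, p.cleithrum_depression_amp),
        }.items():
            exc = acs_excursions(
                clean_pipeline["body_pose"],
                clean_pipeline["trajs"][marker],
                baseline_window=20,
            )
            assert np.nanmax(exc.retraction) == pytest.approx(r_amp, abs=1e-6)
            assert np.nanmax(exc.depression) == pytest.approx(d_amp, abs=1e-6)


class TestElevation:
    def test_identity_relative_rotation_is_zero(self):
        T = 25
        elev = jcs_elevation(identity_pose(T), identity_pose(T, "n"), 10)
        assert np.max(np.abs(elev.angle_deg)) < 1e-12

    def test_constructed_y_rotation_recovered(self):
        """Pure 10-degree rotation about the ACS Y axis reads as 10 degrees."""
        T = 30
        body = identity_pose(T)
        R = np.tile(np.eye(3), (T, 1, 1))
        R[20:] = Rotation.from_euler("y", 10, degrees=True).as_matrix()
        neuro = RigidBodyPose("n", R, np.zeros((T, 3)), np.zeros(T),
                              np.zeros(T, dtype=bool))
        elev = jcs_elevation(body, neuro, 10)
        assert elev.angle_deg[25] == pytest.approx(10.0, abs=1e-9)
        assert np.max(np.abs(elev.angle_deg[:20])) < 1e-9

    def test_pure_y_motion_has_no_crosstalk(self):
        """For pure Y rotations the Z and X angles of the Z-Y-X split are 0."""
        T = 10
        body = identity_pose(T)
        angles = np.linspace(0, 40, T)
        R = Rotation.from_euler("y", angles[:, None], degrees=True).as_matrix()
        neuro = RigidBodyPose("n", R, np.zeros((T, 3)), np.zeros(T),
                              np.zeros(T, dtype=bool))
        elev = jcs_elevation(body, neuro, baseline_window=1)
        assert np.allclose(elev.angle_deg, angles, atol=1e-9)

    def test_generator_closure(self, clean_pipeline):
        truth = clean_pipeline["truth"]
        elev = jcs_elevation(
            clean_pipeline["body_pose"], clean_pipeline["neuro_pose"], 20
        )
        assert np.nanmax(elev.angle_deg) == pytest.approx(
            truth.params.elevation_amp, abs=1e-6
        )
        assert not elev.gimbal_flag.any()

    def test_frame_invariance_of_whole_scene(self, clean_pipeline, rng):
        """A rigid motion of the entire scene leaves elevation unchanged."""
        body, neuro = clean_pipeline["body_pose"], clean_pipeline["neuro_pose"]
        base = jcs_elevation(body, neuro, 20).angle_deg
        T_R = Rotation.from_euler("xyz", [15, -25, 40], degrees=True).as_matrix()
        T_t = np.array([100.0, -50.0, 30.0])

        def moved(p):
            return RigidBodyPose(
                p.body_id,
                np.einsum("ij,fjk->fik", T_R, p.rotation),
                p.translation @ T_R.T + T_t,
                p.residual,
                p.missing,
                p.degenerate,
            )

        shifted = jcs_elevation(moved(body), moved(neuro), 20).angle_deg
        assert np.nanmax(np.abs(shifted - base)) < 1e-9


class TestPeakGape:
    def test_unimodal_series_peak_found(self):
        t = np.arange(100) / 500.0
        d = 4 + 6 * raised_cosine(t, 0.1, 0.08)
        ev = detect_peak_gape(d, 500.0, smooth=False)
        assert ev.frame("peak_gape") == 50
        assert ev.t_peak_gape == pytest.approx(0.1)

    def test_plateau_tie_takes_earliest_frame(self):
        d = np.zeros(100)
        d[50:53] = 7.0
        ev = detect_peak_gape(d, 500.0, smooth=False)
        assert ev.frame("peak_gape") == 50

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="finite"):
            detect_peak_gape(np.full(50, np.nan), 500.0)

    def test_noisy_detection_within_two_frames(self, rng):
        """1% noise, smoothing on: detected within +/-2 frames >= 95% of runs."""
        t = np.arange(100) / 500.0
        clean = 4 + 6 * raised_cosine(t, 0.1, 0.08)
        sd = 0.01 * np.ptp(clean)
        hits = 0
        n = 500
        for _ in range(n):
            ev = detect_peak_gape(clean + rng.normal(0, sd, clean.shape), 500.0)
            hits += abs(ev.frame("peak_gape") - 50) <= 2
        assert hits / n >= 0.95


class TestSummary:
    def test_latency_arithmetic(self):
        """A peak 16 ms after the event reports +16 ms latency."""
        T = 100
        frame_rate = 500.0
        ret = np.zeros(T)
        ret[58] = 2.0  # peak gape at frame 50 -> +8 frames = +16 ms
        from vromm.kinematics import ExcursionSeries

        exc = ExcursionSeries("u", ret, np.zeros(T), slice(0, 20))
        events = EventTable({"peak_gape": (50, 0.1)})
        df = summarize_trial({"u": exc}, None, events, frame_rate)
        row = df[df.variable == "u_retraction"].iloc[0]
        assert row.peak == pytest.approx(2.0)
        assert row.latency_ms == pytest.approx(16.0)

    def test_static_trial_reports_zero_peaks(self):
        from vromm.kinematics import ExcursionSeries

        T = 50
        exc = ExcursionSeries("u", np.zeros(T), np.zeros(T), slice(0, 10))
        events = EventTable({"peak_gape": (25, 0.05)})
        df = summarize_trial({"u": exc}, None, events, 500.0)
        assert (df.peak == 0).all()
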