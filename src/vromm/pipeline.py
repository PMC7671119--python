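"""End-to-end orchestration: files in, kinematic and strain reports out.

`run_trial` chains the full reconstruction for one feeding trial:
calibrated cameras (DLT coefficients or control points) + per-camera 2D
marker tracks -> triangulated 3D trajectories -> gap filling -> rigid-body
poses for the neurocranium and body plane -> ACS excursions and JCS
elevation -> muscle strain and shortening velocity -> a per-trial summary
of peaks and event-relative latencies, plus a tracking-precision report
and QC flags.

`run_validation_experiment` mirrors the method-evaluation design: paired
external/internal strain series for several strikes (simulated with a
known skin-slip attenuation, or loaded from files), regressed per trial
and pooled into accuracy and precision estimates.

`simulate_trial_files` writes a complete synthetic trial to disk in the
pipeline's own file dialects, so a round trip through the file formats is
itself testable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as vio
from .cameras import CameraModel, MarkerTrajectory3D, calibrate_dlt, triangulate_tracks
from .kinematics import (
    DEFAULT_BASELINE_FRAMES,
    ElevationSeries,
    EventTable,
    ExcursionSeries,
    acs_excursions,
    detect_peak_gape,
    jcs_elevation,
    summarize_trial,
)
from .rigid_body import (
    PrecisionReport,
    RigidBodyDef,
    RigidBodyPose,
    fill_gaps,
    fit_body_plane,
    fit_rigid_poses,
    pairwise_distance_precision,
)
from .strain import (
    DEFAULT_FILTER_CUTOFF_HZ,
    StrainSeries,
    compute_muscle_strain,
    muscle_length,
    peak_strain_and_velocity,
)
from .synthetic import (
    GroundTruth,
    StrikeParams,
    make_camera_rig,
    render_observations,
    simulate_strike,
)
from .validation import (
    RegressionResult,
    ValidationReport,
    compare_strain_methods,
    pool_validation_trials,
)

__all__ = [
    "TrialConfig",
    "TrialReport",
    "run_trial",
    "run_validation_experiment",
    "simulate_trial_files",
]

log = logging.getLogger("vromm")


@dataclass
class TrialConfig:
    """Everything needed to process one trial.

    ``role_map`` assigns markers to roles: keys ``neurocranium`` (list),
    ``body_plane`` (list), ``urohyal``/``cleithrum`` (marker names),
    ``muscles`` (muscle id -> [marker_a, marker_b]) and optionally
    ``jaw_pair`` ([upper, lower], used to auto-detect peak gape when no
    events file provides it).
    """

    points2d_csvs: Sequence[str | Path]
    role_map: Mapping
    frame_rate: float
    dlt_csv: str | Path | None = None
    control_points: Mapping | None = None  # {"object_csv": ..., "image_csvs": {...}}
    body_defs: Mapping[str, str | Path] = field(default_factory=dict)
    events_csv: str | Path | None = None
    baseline_frames: int = DEFAULT_BASELINE_FRAMES
    filter_cutoff_hz: float | None = DEFAULT_FILTER_CUTOFF_HZ
    max_gap: int = 5
    output_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.dlt_csv is None) == (self.control_points is None):
            raise ValueError("provide exactly one of dlt_csv or control_points")
        rm = self.role_map
        if "body_plane" not in rm or len(rm["body_plane"]) < 5:
            raise ValueError("role_map.body_plane must list >= 5 markers")
        if "neurocranium" not in rm or len(rm["neurocranium"]) < 3:
            raise ValueError("role_map.neurocranium must list >= 3 markers")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialConfig":
        raw = vio.read_yaml(path)
        base = Path(path).parent

        def _p(v):
            return None if v is None else str((base / v) if not Path(v).is_absolute() else v)

        raw["points2d_csvs"] = [_p(v) for v in raw["points2d_csvs"]]
        for key in ("dlt_csv", "events_csv", "output_dir"):
            if raw.get(key) is not None:
                raw[key] = _p(raw[key])
        if raw.get("body_defs"):
            raw["body_defs"] = {k: _p(v) for k, v in raw["body_defs"].items()}
        return cls(**raw)


@dataclass
class TrialReport:
    """Numeric products of one trial run."""

    trajectories: dict[str, MarkerTrajectory3D]
    body_pose: RigidBodyPose
    neuro_pose: RigidBodyPose
    excursions: dict[str, ExcursionSeries]
    elevation: ElevationSeries
    strains: dict[str, StrainSeries]
    strain_peaks: dict[str, dict]
    events: EventTable
    precision: PrecisionReport
    summary: pd.DataFrame
    qc: dict

    @property
    def has_flags(self) -> bool:
        return any(v for v in self.qc.values() if isinstance(v, (int, np.integer)) and v)


def _load_cameras(config: TrialConfig) -> list[CameraModel]:
    if config.dlt_csv is not None:
        return vio.read_dlt_csv(config.dlt_csv)
    cp = config.control_points
    obj = pd.read_csv(cp["object_csv"], comment="#")
    object_coords = obj[["x", "y", "z"]].to_numpy(float)
    from .cameras import ControlPointSet

    cams = []
    for cam_id, path in cp["image_csvs"].items():
        df = pd.read_csv(path, comment="#")
        pts = ControlPointSet(
            object_coords=object_coords,
            image_coords={cam_id: df[["u", "v"]].to_numpy(float)},
        )
        model, rmse, _ = calibrate_dlt(pts, cam_id)
        log.info("calibrated %s: reprojection RMSE %.4f px", cam_id, rmse)
        cams.append(model)
    return cams


def _body_def_from_config(
    config: TrialConfig,
    body_id: str,
    marker_ids: Sequence[str],
    trajectories: Mapping[str, MarkerTrajectory3D],
) -> RigidBodyDef:
    """Reference coordinates from file, or bootstrapped from the baseline.

    Real experiments supply CT-derived reference coordinates; when absent,
    the mean triangulated positions over the (static) baseline window are
    used as the reference configuration.
    """
    if body_id in config.body_defs:
        return vio.read_body_def_csv(config.body_defs[body_id], body_id)
    ref = []
    for m in marker_ids:
        xyz = trajectories[m].xyz[: config.baseline_frames]
        ok = np.all(np.isfinite(xyz), axis=1)
        if not ok.any():
            raise ValueError(
                f"marker {m!r} missing throughout the baseline; cannot bootstrap "
                f"a reference for body {body_id!r}"
            )
        ref.append(xyz[ok].mean(axis=0))
    return RigidBodyDef(body_id=body_id, marker_ids=marker_ids, reference=np.asarray(ref))


def run_trial(config: TrialConfig) -> TrialReport:
    """Run the full reconstruction for one trial.

    Fails fast on schema problems (missing marker columns, malformed
    files); per-frame data problems (gaps, low-confidence triangulation,
    gimbal proximity) are flagged in ``report.qc`` and the run continues.
    """
    cameras = _load_cameras(config)
    tracks = vio.read_points2d_csv(*config.points2d_csvs)
    for cam in cameras:
        if cam.id not in tracks:
            raise ValueError(f"2D data has no columns for camera {cam.id!r}")

    rm = config.role_map
    mapped = set(rm["neurocranium"]) | set(rm["body_plane"])
    for key in ("urohyal", "cleithrum"):
        if key in rm:
            mapped.add(rm[key])
    for pair in rm.get("muscles", {}).values():
        mapped.update(pair)
    if rm.get("jaw_pair"):
        mapped.update(rm["jaw_pair"])
    available = set.union(*(set(t) for t in tracks.values()))
    missing_markers = mapped - available
    if missing_markers:
        raise ValueError(
            f"2D data is missing mapped marker(s): {sorted(missing_markers)}"
        )

    trajs = triangulate_tracks(cameras, tracks)
    trajs = {m: fill_gaps(tr, config.max_gap) for m, tr in trajs.items()}

    neuro_def = _body_def_from_config(config, "neurocranium", rm["neurocranium"], trajs)
    body_def = _body_def_from_config(config, "body_plane", rm["body_plane"], trajs)
    neuro_pose = fit_rigid_poses(neuro_def, trajs)
    body_pose = fit_body_plane(body_def, trajs)

    bl = config.baseline_frames
    excursions = {}
    for key in ("urohyal", "cleithrum"):
        if key in rm:
            excursions[key] = acs_excursions(body_pose, trajs[rm[key]], bl)
    elevation = jcs_elevation(body_pose, neuro_pose, bl)

    if config.events_csv is not None:
        events = vio.read_events_csv(config.events_csv)
        if "peak_gape" not in events.events:
            raise ValueError("events CSV must contain a 'peak_gape' event")
    elif rm.get("jaw_pair"):
        a, b = rm["jaw_pair"]
        gape = muscle_length(trajs[a], trajs[b])
        events = detect_peak_gape(gape, config.frame_rate)
        log.info(
            "peak gape auto-detected from jaw pair %s at frame %d",
            rm["jaw_pair"],
            events.frame("peak_gape"),
        )
    else:
        raise ValueError("no events CSV and no jaw_pair in the role map")

    strains = {}
    strain_peaks = {}
    for muscle, (a, b) in rm.get("muscles", {}).items():
        s = compute_muscle_strain(
            muscle,
            trajs[a],
            trajs[b],
            frame_rate=config.frame_rate,
            baseline_window=bl,
            filter_cutoff_hz=config.filter_cutoff_hz,
            marker_pair=(a, b),
        )
        strains[muscle] = s
        strain_peaks[muscle] = peak_strain_and_velocity(
            s.strain_pct, s.velocity, events, config.frame_rate
        )

    precision = pairwise_distance_precision(trajs, rm["neurocranium"])
    summary = summarize_trial(excursions, elevation, events, config.frame_rate)

    qc = {
        "n_gap_filled_frames": int(sum(tr.filled.sum() for tr in trajs.values())),
        "n_low_confidence_frames": int(
            sum(tr.low_confidence.sum() for tr in trajs.values())
        ),
        "n_missing_3d_frames": int(sum(tr.missing.sum() for tr in trajs.values())),
        "n_gimbal_flagged_frames": int(elevation.gimbal_flag.sum()),
        "n_degenerate_pose_frames": int(
            body_pose.degenerate.sum() + neuro_pose.degenerate.sum()
        ),
    }

    report = TrialReport(
        trajectories=trajs,
        body_pose=body_pose,
        neuro_pose=neuro_pose,
        excursions=excursions,
        elevation=elevation,
        strains=strains,
        strain_peaks=strain_peaks,
        events=events,
        precision=precision,
        summary=summary,
        qc=qc,
    )
    if config.output_dir is not None:
        _write_trial_outputs(report, config)
    return report


def _pose_frame(pose: RigidBodyPose) -> pd.DataFrame:
    cols = {}
    for i in range(3):
        for j in range(3):
            cols[f"R{i + 1}{j + 1}"] = pose.rotation[:, i, j]
    for i, ax in enumerate("XYZ"):
        cols[f"t{ax}_mm"] = pose.translation[:, i]
    cols["residual_mm"] = pose.residual
    return pd.DataFrame(cols)


def _write_trial_outputs(report: TrialReport, config: TrialConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    vio.write_trajectories3d_csv(out / "trajectories3d.csv", report.trajectories)
    for name, pose in (("body_plane", report.body_pose), ("neurocranium", report.neuro_pose)):
        df = _pose_frame(pose)
        with open(out / f"pose_{name}.csv", "w", newline="") as fh:
            fh.write("# units: rotation dimensionless, translation mm, residual mm\n")
            df.to_csv(fh, index=False, float_format="%.12g")
    kin = {"frame": np.arange(report.body_pose.n_frames)}
    for name, exc in report.excursions.items():
        kin[f"{name}_retraction_mm"] = exc.retraction
        kin[f"{name}_depression_mm"] = exc.depression
    kin["elevation_deg"] = report.elevation.angle_deg
    with open(out / "kinematics.csv", "w", newline="") as fh:
        fh.write("# units: excursions mm, elevation deg; baseline-zeroed\n")
        pd.DataFrame(kin).to_csv(fh, index=False, float_format="%.12g")
    for muscle, s in report.strains.items():
        df = pd.DataFrame(
            {
                "length_mm": s.length_mm,
                "normalized_length": s.normalized_length,
                "strain_pct": s.strain_pct,
                "velocity_Li_per_s": s.velocity,
            }
        )
        with open(out / f"strain_{muscle}.csv", "w", newline="") as fh:
            fh.write(
                f"# units: length mm, strain % of L_i={s.L_i_mm:.6g} mm, "
                "velocity L_i/s (shortening positive)\n"
            )
            df.to_csv(fh, index=False, float_format="%.12g")
    with open(out / "summary.csv", "w", newline="") as fh:
        fh.write("# units: excursion peaks mm, elevation deg, latencies ms\n")
        report.summary.to_csv(fh, index=False, float_format="%.12g")
    vio.write_events_csv(out / "events.csv", report.events)
    summary_json = {
        "events": {k: {"frame": f, "time_s": t} for k, (f, t) in report.events.events.items()},
        "precision_mean_sd_mm": report.precision.mean_sd,
        "precision_n_pairs": report.precision.n_pairs,
        "strain_peaks": {
            m: {k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v))
                for k, v in pk.items()}
            for m, pk in report.strain_peaks.items()
        },
        "qc": report.qc,
        "config": _config_digest(config),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary_json, fh, indent=2, sort_keys=True)


def _config_digest(config: TrialConfig) -> dict:
    d = dataclasses.asdict(config)
    d = {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}
    d["points2d_csvs"] = [str(p) for p in config.points2d_csvs]
    return json.loads(json.dumps(d, default=str))


def simulate_trial_files(
    out_dir: str | Path,
    params: StrikeParams | None = None,
    n_cameras: int = 2,
    dropout_rate: float = 0.0,
) -> tuple[GroundTruth, list[CameraModel]]:
    """Write a complete synthetic trial to ``out_dir`` in pipeline formats.

    Produces per-camera 2D CSVs, the DLT coefficient file, rigid-body
    definition CSVs, the ground-truth 3D trajectories, the events CSV, the
    strike parameters as YAML, and a ready-to-run ``trial.yaml`` config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = simulate_strike(params)
    p = truth.params
    rig = make_camera_rig(n_cameras)
    obs = render_observations(truth, rig, dropout_rate=dropout_rate)

    points_files = []
    for cam in rig:
        f = out / f"points2d_{cam.id}.csv"
        vio.write_points2d_csv(f, cam.id, obs[cam.id])
        points_files.append(f.name)
    vio.write_dlt_csv(out / "dlt.csv", rig)
    vio.write_body_def_csv(out / "body_neurocranium.csv", truth.neuro_def)
    vio.write_body_def_csv(out / "body_plane.csv", truth.body_def)
    gt_trajs = {
        m: MarkerTrajectory3D(
            marker_id=m, xyz=xyz, residual=np.zeros(len(xyz))
        )
        for m, xyz in truth.markers.items()
    }
    vio.write_trajectories3d_csv(out / "ground_truth_3d.csv", gt_trajs)
    vio.write_events_csv(out / "events.csv", truth.events)
    vio.write_yaml(out / "params.yaml", dataclasses.asdict(p))
    vio.write_yaml(
        out / "trial.yaml",
        {
            "points2d_csvs": points_files,
            "dlt_csv": "dlt.csv",
            "body_defs": {
                "neurocranium": "body_neurocranium.csv",
                "body_plane": "body_plane.csv",
            },
            "events_csv": "events.csv",
            "role_map": truth.role_map,
            "frame_rate": p.frame_rate,
            "baseline_frames": DEFAULT_BASELINE_FRAMES,
            "output_dir": "out",
            "seed": p.seed,
        },
    )
    return truth, rig


def run_validation_experiment(
    n_trials: int = 7,
    skin_slip_alpha: float = 0.90,
    strain_noise_sd_pct: float = 0.5,
    seed: int = 0,
    base_params: StrikeParams | None = None,
    mode: str = "strain",
    muscle: str = "sh",
    n_cameras: int = 2,
) -> ValidationReport:
    """Paired external-vs-internal strain comparison over simulated strikes.

    The default design mirrors the method-evaluation experiment: 7 feeding
    strikes from one individual, external strain attenuated by a skin-slip
    factor and perturbed by Gaussian measurement noise on the strain scale,
    regressed per strike against the internal (reference-method) strain.

    ``mode="strain"`` compares the generator's strain series directly
    (noise injected on the strain scale, as stated); ``mode="pipeline"``
    instead renders noisy 2D observations and pushes them through
    triangulation and marker-distance strain estimation, exercising the
    whole reconstruction chain.
    """
    if n_trials < 1:
        raise ValueError("need at least one paired trial")
    if mode not in ("strain", "pipeline"):
        raise ValueError(f"unknown mode {mode!r}")
    base = base_params if base_params is not None else StrikeParams()
    rng = np.random.default_rng(seed)
    results: list[RegressionResult] = []
    for i in range(n_trials):
        params = replace(
            base, skin_slip_alpha=skin_slip_alpha, seed=int(rng.integers(2**31))
        )
        truth = simulate_strike(params)
        internal = truth.internal_strain[muscle]
        if mode == "strain":
            external = truth.external_strain[muscle] + rng.normal(
                0.0, strain_noise_sd_pct, size=internal.shape
            )
        else:
            rig = make_camera_rig(n_cameras)
            obs = render_observations(truth, rig, seed=params.seed)
            trajs = triangulate_tracks(rig, obs)
            a, b = truth.role_map["muscles"][muscle]
            s = compute_muscle_strain(
                muscle,
                trajs[a],
                trajs[b],
                frame_rate=params.frame_rate,
                filter_cutoff_hz=None,
            )
            external = s.strain_pct + rng.normal(
                0.0, strain_noise_sd_pct, size=internal.shape
            )
        results.append(compare_strain_methods(external, internal))
    return pool_validation_trials(results)
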