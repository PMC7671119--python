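"""Skeletal kinematics in the body-plane anatomical frame.

Suction-feeding expansion is described relative to the fish's own body: an
anatomical coordinate system (ACS) parented to the moving body plane, with
+X rostral, +Y left-lateral and +Z dorsal.  Urohyal and cleithrum marker
motion is decomposed into retraction (caudad translation, reported as
minus the ACS X displacement) and depression (ventrad translation, minus
the ACS Z displacement).  Neurocranial elevation is the rotation of the
neurocranium about the ACS Y axis relative to the body plane, measured
with a joint coordinate system (JCS) and reported in degrees, dorsal
rotation positive.  All series are zeroed on a pre-strike baseline window,
and peak gape serves as time zero for event-relative timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.spatial.transform import Rotation

from .cameras import MarkerTrajectory3D
from .rigid_body import RigidBodyPose

__all__ = [
    "ExcursionSeries",
    "ElevationSeries",
    "EventTable",
    "acs_excursions",
    "jcs_elevation",
    "detect_peak_gape",
    "summarize_trial",
    "DEFAULT_BASELINE_FRAMES",
]

#: default pre-strike baseline: the first 20 frames of a trial
DEFAULT_BASELINE_FRAMES = 20

#: |elevation| above this flags gimbal proximity in the Euler decomposition
GIMBAL_LIMIT_DEG = 89.0


@dataclass
class ExcursionSeries:
    """Retraction/depression (mm) of one marker relative to the body plane."""

    marker_id: str
    retraction: np.ndarray  # mm, caudad positive
    depression: np.ndarray  # mm, ventrad positive
    baseline: slice
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.missing is None:
            self.missing = ~np.isfinite(self.retraction)


@dataclass
class ElevationSeries:
    """Neurocranial elevation (degrees, dorsal positive) vs the body plane."""

    angle_deg: np.ndarray
    baseline: slice
    gimbal_flag: np.ndarray
    missing: np.ndarray


@dataclass
class EventTable:
    """Named trial events with frame index and time in seconds."""

    events: dict[str, tuple[int, float]]

    def frame(self, name: str) -> int:
        return self.events[name][0]

    def time(self, name: str) -> float:
        return self.events[name][1]

    @property
    def t_peak_gape(self) -> float:
        return self.time("peak_gape")


def _baseline_slice(baseline_window: slice | int | None, n: int) -> slice:
    if baseline_window is None:
        baseline_window = DEFAULT_BASELINE_FRAMES
    if isinstance(baseline_window, int):
        baseline_window = slice(0, baseline_window)
    if baseline_window.stop is None or baseline_window.stop <= (baseline_window.start or 0):
        raise ValueError("baseline window must be non-empty")
    if (baseline_window.start or 0) >= n:
        raise ValueError("baseline window lies outside the trial")
    return slice(baseline_window.start or 0, min(baseline_window.stop, n))


def _body_frame_coords(
    body_pose: RigidBodyPose, xyz: np.ndarray
) -> np.ndarray:
    """World marker coordinates expressed in the per-frame body (ACS) frame."""
    rel = xyz - body_pose.translation
    # q = R^T (x - t), batched over frames
    return np.einsum("fji,fj->fi", body_pose.rotation, rel)


def acs_excursions(
    body_pose: RigidBodyPose,
    marker: MarkerTrajectory3D,
    baseline_window: slice | int | None = None,
) -> ExcursionSeries:
    """Decompose marker motion into retraction and depression in the ACS.

    The marker's world trajectory is re-expressed in the per-frame body
    plane frame, so common whole-body motion (swimming through the tank)
    cancels.  Retraction is the negated, baseline-zeroed ACS X coordinate;
    depression the negated, baseline-zeroed ACS Z coordinate — both
    positive during suction expansion per the standard sign convention.
    """
    if body_pose.n_frames != marker.n_frames:
        raise ValueError("pose and marker series must share frames")
    bl = _baseline_slice(baseline_window, marker.n_frames)
    q = _body_frame_coords(body_pose, marker.xyz)
    ok_bl = np.all(np.isfinite(q[bl]), axis=1)
    if not ok_bl.any():
        raise ValueError(
            f"marker {marker.marker_id!r} missing throughout the baseline window"
        )
    base = q[bl][ok_bl].mean(axis=0)
    retraction = -(q[:, 0] - base[0])
    depression = -(q[:, 2] - base[2])
    return ExcursionSeries(
        marker_id=marker.marker_id,
        retraction=retraction,
        depression=depression,
        baseline=bl,
    )


def jcs_elevation(
    body_pose: RigidBodyPose,
    neuro_pose: RigidBodyPose,
    baseline_window: slice | int | None = None,
    sequence: str = "ZYX",
) -> ElevationSeries:
    """Neurocranial elevation relative to the body plane via a JCS.

    The relative rotation ``R_rel = R_body^T R_neuro`` is referenced to its
    mean over the baseline window (so elevation is zero at rest regardless
    of how the neurocranium's reference frame is oriented) and decomposed
    in Z-Y-X order; elevation is the Y-axis angle in degrees, dorsal
    rotation positive.  Frames with |elevation| > 89 deg are flagged as
    gimbal-proximal; the middle Euler angle degenerates there.
    """
    if body_pose.n_frames != neuro_pose.n_frames:
        raise ValueError("pose series must share frames")
    T = body_pose.n_frames
    bl = _baseline_slice(baseline_window, T)
    ok = (
        ~body_pose.missing
        & ~neuro_pose.missing
        & ~body_pose.degenerate
        & ~neuro_pose.degenerate
    )
    rel = np.full((T, 3, 3), np.nan)
    rel[ok] = np.einsum(
        "fji,fjk->fik", body_pose.rotation[ok], neuro_pose.rotation[ok]
    )
    ok_bl = ok[bl]
    if not ok_bl.any():
        raise ValueError("no valid pose in the baseline window")
    R_base = Rotation.from_matrix(rel[bl][ok_bl]).mean()
    angle = np.full(T, np.nan)
    if ok.any():
        motion = Rotation.from_matrix(rel[ok]) * R_base.inv()
        eul = motion.as_euler(sequence, degrees=True)
        angle[ok] = eul[:, sequence.upper().index("Y")]
    gimbal = np.zeros(T, dtype=bool)
    gimbal[ok] = np.abs(angle[ok]) > GIMBAL_LIMIT_DEG
    return ElevationSeries(angle_deg=angle, baseline=bl, gimbal_flag=gimbal, missing=~ok)


def detect_peak_gape(
    jaw_distance: np.ndarray,
    frame_rate: float,
    smooth: bool = True,
    smooth_window: int = 9,
) -> EventTable:
    """Locate peak gape as the global maximum of the jaw-pair distance.

    A light zero-phase Savitzky-Golay smooth (quadratic, ``smooth_window``
    frames) suppresses tracking noise before the argmax; ties resolve to
    the earliest frame.  Returns an event table with the ``peak_gape``
    entry.
    """
    d = np.asarray(jaw_distance, dtype=float)
    finite = np.isfinite(d)
    if finite.sum() < 3:
        raise ValueError("jaw-distance series needs >= 3 finite frames")
    work = d.copy()
    if smooth:
        # interpolate across missing frames so the filter stays well-defined
        idx = np.arange(len(d))
        work = np.interp(idx, idx[finite], d[finite])
        win = min(smooth_window, len(work) if len(work) % 2 == 1 else len(work) - 1)
        if win >= 5:
            work = savgol_filter(work, window_length=win, polyorder=2)
        work[~finite] = -np.inf
    else:
        work[~finite] = -np.inf
    frame = int(np.argmax(work))
    return EventTable(events={"peak_gape": (frame, frame / frame_rate)})


def summarize_trial(
    excursions: Mapping[str, ExcursionSeries],
    elevation: ElevationSeries | None,
    events: EventTable,
    frame_rate: float,
) -> pd.DataFrame:
    """Per-trial peak magnitudes and their timing relative to peak gape.

    Returns a table with one row per kinematic variable (``<marker>_retraction``
    and ``<marker>_depression`` in mm, ``elevation`` in degrees), the peak
    value, its frame, and its latency after peak gape in milliseconds.
    """
    t_pg = events.t_peak_gape
    rows = []

    def _peak_row(name: str, series: np.ndarray, unit: str) -> None:
        finite = np.isfinite(series)
        if not finite.any():
            rows.append((name, unit, np.nan, -1, np.nan))
            return
        masked = np.where(finite, series, -np.inf)
        f = int(np.argmax(masked))
        rows.append((name, unit, float(series[f]), f, (f / frame_rate - t_pg) * 1e3))

    for name, exc in excursions.items():
        _peak_row(f"{name}_retraction", exc.retraction, "mm")
        _peak_row(f"{name}_depression", exc.depression, "mm")
    if elevation is not None:
        _peak_row("elevation", elevation.angle_deg, "deg")
    return pd.DataFrame(
        rows, columns=["variable", "unit", "peak", "peak_frame", "latency_ms"]
    )
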