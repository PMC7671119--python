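"""DLT camera calibration and multi-view triangulation.

The camera model is the classic 11-parameter direct linear transformation
(DLT) used throughout X-ray and video reconstruction of moving morphology
(XROMM/VROMM) workflows::

    u = (L1*X + L2*Y + L3*Z + L4) / (L9*X + L10*Y + L11*Z + 1)
    v = (L5*X + L6*Y + L7*Z + L8) / (L9*X + L10*Y + L11*Z + 1)

with world coordinates in millimetres and image coordinates in pixels.
Calibration solves for the 11 coefficients per camera from control points
of known 3D position (the "calibration object"); triangulation inverts the
model to recover 3D marker positions from two or more synchronized views.

Refraction through water and lens distortion are not modelled explicitly;
at the working distances and noise levels considered here the linear DLT
absorbs them approximately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CameraModel",
    "ControlPointSet",
    "MarkerTrajectory3D",
    "CalibrationError",
    "ProjectionError",
    "calibrate_dlt",
    "project",
    "triangulate",
    "triangulate_tracks",
]

#: rays closer to parallel than this (condition number of the triangulation
#: normal system) are flagged low-confidence
CONDITION_THRESHOLD = 1e6


class CalibrationError(ValueError):
    """Raised for degenerate control-point configurations."""


class ProjectionError(ValueError):
    """Raised when a point projects to infinity (denominator ~ 0)."""


@dataclass(frozen=True)
class CameraModel:
    """An 11-parameter DLT camera.

    Parameters
    ----------
    dlt
        Coefficients ``(L1, ..., L11)``.
    image_size
        Sensor size ``(width, height)`` in pixels.
    id
        Camera label used in CSV headers.
    """

    dlt: np.ndarray
    image_size: tuple[int, int] = (1024, 1024)
    id: str = "cam1"

    def __post_init__(self) -> None:
        dlt = np.asarray(self.dlt, dtype=float).reshape(11)
        if not np.all(np.isfinite(dlt)):
            raise ValueError("DLT coefficients must be finite")
        object.__setattr__(self, "dlt", dlt)

    @property
    def matrix(self) -> np.ndarray:
        """The 3x4 homogeneous projection matrix (last entry fixed to 1)."""
        L = self.dlt
        return np.array(
            [
                [L[0], L[1], L[2], L[3]],
                [L[4], L[5], L[6], L[7]],
                [L[8], L[9], L[10], 1.0],
            ]
        )


@dataclass
class ControlPointSet:
    """Calibration correspondences: 3D object points and their 2D detections.

    ``image_coords`` maps a camera id to an ``(N, 2)`` pixel array aligned
    row-by-row with ``object_coords``; NaN rows mark points not detected in
    that view.
    """

    object_coords: np.ndarray
    image_coords: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        self.object_coords = np.asarray(self.object_coords, dtype=float)
        if self.object_coords.ndim != 2 or self.object_coords.shape[1] != 3:
            raise ValueError("object_coords must be (N, 3)")
        self.image_coords = {
            k: np.asarray(v, dtype=float) for k, v in self.image_coords.items()
        }
        n = len(self.object_coords)
        for cam, uv in self.image_coords.items():
            if uv.shape != (n, 2):
                raise ValueError(
                    f"image_coords[{cam!r}] must be ({n}, 2), got {uv.shape}"
                )


@dataclass
class MarkerTrajectory3D:
    """Per-frame 3D position of one marker with quality flags.

    ``xyz`` is ``(T, 3)`` in mm with NaN rows where the marker could not be
    reconstructed; ``residual`` is the RMS reprojection error (px) of the
    triangulation, NaN on missing frames.
    """

    marker_id: str
    xyz: np.ndarray
    residual: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]
    low_confidence: np.ndarray = field(default=None)  # type: ignore[assignment]
    filled: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.residual = np.asarray(self.residual, dtype=float)
        if self.missing is None:
            self.missing = ~np.all(np.isfinite(self.xyz), axis=1)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.low_confidence is None:
            self.low_confidence = np.zeros(len(self.xyz), dtype=bool)
        if self.filled is None:
            self.filled = np.zeros(len(self.xyz), dtype=bool)
        ok = ~self.missing
        if np.any(self.residual[ok] < 0):
            raise ValueError("triangulation residuals must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.xyz)


def project(camera: CameraModel, points: np.ndarray) -> np.ndarray:
    """Project 3D world points (mm) to pixel coordinates via the DLT.

    Parameters
    ----------
    camera
        The camera model.
    points
        ``(3,)`` or ``(N, 3)`` world coordinates.

    Returns
    -------
    ``(2,)`` or ``(N, 2)`` pixel coordinates.

    Raises
    ------
    ProjectionError
        If the projective denominator vanishes at any point (point at
        infinity for this camera).
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    L = camera.dlt
    den = pts @ L[8:11] + 1.0
    if np.any(np.abs(den) < 1e-12):
        raise ProjectionError(
            f"point at infinity for camera {camera.id!r}: DLT denominator ~ 0"
        )
    u = (pts @ L[0:3] + L[3]) / den
    v = (pts @ L[4:7] + L[7]) / den
    uv = np.stack([u, v], axis=-1)
    return uv[0] if single else uv


def _check_noncoplanar(points: np.ndarray, tol: float = 1e-8) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] <= 0 or s[2] / s[0] < tol:
        raise CalibrationError(
            "control points are (nearly) coplanar: the 11-parameter DLT is "
            "degenerate; use a 3D calibration object"
        )


def calibrate_dlt(
    points: ControlPointSet, camera_id: str, image_size: tuple[int, int] = (1024, 1024)
) -> tuple[CameraModel, float, np.ndarray]:
    """Fit the 11 DLT coefficients for one camera by linear least squares.

    Each visible control point contributes two rows to the linear system
    obtained by multiplying the projection equations through by the
    denominator.  Requires at least 6 non-coplanar points visible in the
    camera (11 unknowns / 2 equations per point).

    Returns
    -------
    (model, rmse, per_point_errors)
        ``rmse`` is the root-mean-square reprojection error in pixels over
        the points used; ``per_point_errors`` is the per-point reprojection
        distance (px), NaN where the point was not visible.
    """
    if camera_id not in points.image_coords:
        raise CalibrationError(f"no image coordinates for camera {camera_id!r}")
    uv = points.image_coords[camera_id]
    xyz = points.object_coords
    visible = np.all(np.isfinite(uv), axis=1) & np.all(np.isfinite(xyz), axis=1)
    n_vis = int(visible.sum())
    if n_vis < 6:
        raise CalibrationError(
            f"camera {camera_id!r}: {n_vis} control points visible, need >= 6"
        )
    X = xyz[visible]
    U = uv[visible]
    _check_noncoplanar(X)

    n = len(X)
    A = np.zeros((2 * n, 11))
    b = np.empty(2 * n)
    A[0::2, 0:3] = X
    A[0::2, 3] = 1.0
    A[0::2, 8:11] = -U[:, 0:1] * X
    A[1::2, 4:7] = X
    A[1::2, 7] = 1.0
    A[1::2, 8:11] = -U[:, 1:2] * X
    b[0::2] = U[:, 0]
    b[1::2] = U[:, 1]
    coeffs, *_ = np.linalg.lstsq(A, b, rcond=None)

    model = CameraModel(dlt=coeffs, image_size=image_size, id=camera_id)
    reproj = project(model, X)
    err_vis = np.linalg.norm(reproj - U, axis=1)
    rmse = float(np.sqrt(np.mean(err_vis**2)))
    per_point = np.full(len(xyz), np.nan)
    per_point[visible] = err_vis
    return model, rmse, per_point


def triangulate(
    cameras: Sequence[CameraModel],
    observations: Sequence[np.ndarray | None],
) -> tuple[np.ndarray, float, bool]:
    """Intersect DLT rays from >= 2 cameras to recover a 3D point.

    Parameters
    ----------
    cameras
        Camera models, one per view.
    observations
        Per-camera ``(u, v)`` pixel observations aligned with ``cameras``;
        ``None`` or a NaN pair marks a missing observation.

    Returns
    -------
    (xyz, residual, low_confidence)
        ``xyz`` is NaN-filled when fewer than two cameras observe the point
        (a missing frame, not an error).  ``residual`` is the RMS
        reprojection error (px) over contributing cameras.
        ``low_confidence`` flags near-parallel ray geometry.
    """
    if len(cameras) != len(observations):
        raise ValueError("cameras and observations must align")
    rows = []
    rhs = []
    used: list[tuple[CameraModel, np.ndarray]] = []
    for cam, obs in zip(cameras, observations):
        if obs is None:
            continue
        obs = np.asarray(obs, dtype=float).reshape(2)
        if not np.all(np.isfinite(obs)):
            continue
        L = cam.dlt
        u, v = obs
        rows.append([L[0] - u * L[8], L[1] - u * L[9], L[2] - u * L[10]])
        rows.append([L[4] - v * L[8], L[5] - v * L[9], L[6] - v * L[10]])
        rhs.extend([u - L[3], v - L[7]])
        used.append((cam, obs))
    if len(used) < 2:
        return np.full(3, np.nan), float("nan"), False

    A = np.asarray(rows)
    b = np.asarray(rhs)
    xyz, *_ = np.linalg.lstsq(A, b, rcond=None)
    cond = np.linalg.cond(A)
    low_confidence = bool(cond > CONDITION_THRESHOLD)

    sq = 0.0
    for cam, obs in used:
        err = project(cam, xyz) - obs
        sq += float(err @ err)
    residual = float(np.sqrt(sq / len(used)))
    return xyz, residual, low_confidence


def triangulate_tracks(
    cameras: Sequence[CameraModel],
    tracks: Mapping[str, Mapping[str, np.ndarray]],
) -> dict[str, MarkerTrajectory3D]:
    """Triangulate full 2D marker tracks into 3D trajectories.

    Parameters
    ----------
    cameras
        The calibrated cameras.
    tracks
        ``tracks[camera_id][marker_id]`` is a ``(T, 2)`` pixel track with
        NaN rows for missing frames.  All tracks must share the frame count.

    Returns
    -------
    dict of marker id to :class:`MarkerTrajectory3D`.
    """
    cam_ids = [c.id for c in cameras]
    for cid in cam_ids:
        if cid not in tracks:
            raise ValueError(f"no 2D tracks for camera {cid!r}")
    markers = sorted({m for cid in cam_ids for m in tracks[cid]})
    lengths = {
        tracks[cid][m].shape[0] for cid in cam_ids for m in tracks[cid]
    }
    if len(lengths) != 1:
        raise ValueError(f"2D tracks disagree on frame count: {sorted(lengths)}")
    (T,) = lengths

    out: dict[str, MarkerTrajectory3D] = {}
    for m in markers:
        xyz = np.full((T, 3), np.nan)
        res = np.full(T, np.nan)
        lowc = np.zeros(T, dtype=bool)
        per_cam = [tracks[cid].get(m) for cid in cam_ids]
        for f in range(T):
            obs = [pc[f] if pc is not None else None for pc in per_cam]
            p, r, lc = triangulate(cameras, obs)
            xyz[f] = p
            res[f] = r
            lowc[f] = lc
        out[m] = MarkerTrajectory3D(marker_id=m, xyz=xyz, residual=res,
                                    low_confidence=lowc)
    return out
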