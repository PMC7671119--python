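"""Rigid-body pose fitting and marker-tracking precision.

Markers glued to one bone (or defining the reference body plane) move as a
rigid set: each video frame is related to the reference configuration by a
rotation and a translation.  Poses are recovered by orthogonal Procrustes
(Kabsch/SVD) with a reflection guard, the standard least-squares solution
for marker-based skeletal kinematics.

Tracking precision is quantified the way rigid bodies allow: distances
between markers on one bone are constant in reality, so the standard
deviation over time of each pairwise marker-to-marker distance measures
the combined tracking/reconstruction noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .cameras import MarkerTrajectory3D

__all__ = [
    "RigidBodyDef",
    "RigidBodyPose",
    "PrecisionReport",
    "fit_rigid_pose",
    "fit_rigid_poses",
    "fit_body_plane",
    "canonical_body_frame",
    "pairwise_distance_precision",
    "fill_gaps",
]


@dataclass
class RigidBodyDef:
    """Reference configuration of a marker set treated as rigid.

    ``reference`` holds one fixed M x 3 coordinate set (mm) — from CT marker
    centroids in real experiments, or from the generator for synthetic data.
    """

    body_id: str
    marker_ids: Sequence[str]
    reference: np.ndarray

    def __post_init__(self) -> None:
        self.marker_ids = list(self.marker_ids)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.reference.shape != (len(self.marker_ids), 3):
            raise ValueError("reference must be (len(marker_ids), 3)")
        if len(self.marker_ids) < 3:
            raise ValueError("a rigid body needs >= 3 markers")
        if _collinear(self.reference):
            raise ValueError(f"reference markers of {self.body_id!r} are collinear")


@dataclass
class RigidBodyPose:
    """Per-frame rigid transform mapping reference coordinates to world.

    ``rotation`` is ``(T, 3, 3)`` proper orthogonal, ``translation`` ``(T, 3)``
    in mm; ``residual`` the RMS marker misfit (mm).  ``missing`` marks frames
    with fewer than 3 visible markers, ``degenerate`` frames whose visible
    markers were collinear.
    """

    body_id: str
    rotation: np.ndarray
    translation: np.ndarray
    residual: np.ndarray
    missing: np.ndarray
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.translation), dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.translation)

    def transform(self, points: np.ndarray, frame: int) -> np.ndarray:
        """Map reference-frame points into world coordinates at ``frame``."""
        return points @ self.rotation[frame].T + self.translation[frame]


@dataclass
class PrecisionReport:
    """SD of within-body pairwise marker distances (the precision metric)."""

    pair_ids: list[tuple[str, str]]
    pair_sd: np.ndarray  # mm, one entry per pair
    mean_sd: float  # mm
    n_pairs: int
    excluded_pairs: list[tuple[str, str]]


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return bool(s[0] <= 0 or s[1] / s[0] < tol)


def _kabsch(ref: np.ndarray, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares R, t with det(R)=+1 minimizing sum ||R ref + t - obs||^2."""
    cr = ref.mean(axis=0)
    co = obs.mean(axis=0)
    H = (ref - cr).T @ (obs - co)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = co - R @ cr
    resid = ref @ R.T + t - obs
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return R, t, rms


def fit_rigid_pose(
    body: RigidBodyDef, observed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, str]:
    """Fit one frame's rigid pose from observed marker positions.

    ``observed`` is (M, 3) aligned with ``body.marker_ids``; NaN rows are
    missing markers.  Returns ``(R, t, residual_mm, status)`` with status
    one of ``"ok"``, ``"missing"`` (fewer than 3 visible markers) or
    ``"degenerate"`` (visible markers collinear); for the latter two the
    pose entries are NaN.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.shape != body.reference.shape:
        raise ValueError("observed must match the body's reference shape")
    ok = np.all(np.isfinite(obs), axis=1)
    if ok.sum() < 3:
        return np.full((3, 3), np.nan), np.full(3, np.nan), float("nan"), "missing"
    if _collinear(obs[ok]):
        return np.full((3, 3), np.nan), np.full(3, np.nan), float("nan"), "degenerate"
    R, t, rms = _kabsch(body.reference[ok], obs[ok])
    return R, t, rms, "ok"


def fit_rigid_poses(
    body: RigidBodyDef,
    trajectories: Mapping[str, MarkerTrajectory3D | np.ndarray],
) -> RigidBodyPose:
    """Fit the pose series of a body from its marker trajectories."""
    series = []
    for m in body.marker_ids:
        if m not in trajectories:
            raise ValueError(f"no trajectory for marker {m!r} of body {body.body_id!r}")
        tr = trajectories[m]
        series.append(tr.xyz if isinstance(tr, MarkerTrajectory3D) else np.asarray(tr))
    stacked = np.stack(series, axis=1)  # (T, M, 3)
    T = stacked.shape[0]
    R = np.full((T, 3, 3), np.nan)
    t = np.full((T, 3), np.nan)
    res = np.full(T, np.nan)
    missing = np.zeros(T, dtype=bool)
    degenerate = np.zeros(T, dtype=bool)
    for f in range(T):
        Rf, tf, rf, status = fit_rigid_pose(body, stacked[f])
        R[f], t[f], res[f] = Rf, tf, rf
        missing[f] = status == "missing"
        degenerate[f] = status == "degenerate"
    return RigidBodyPose(
        body_id=body.body_id,
        rotation=R,
        translation=t,
        residual=res,
        missing=missing,
        degenerate=degenerate,
    )


def canonical_body_frame(
    reference: np.ndarray, dorsal_hint: np.ndarray = (0.0, 0.0, 1.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Anatomical axes for the body plane from its marker layout.

    The rostro-caudal principal axis of the markers becomes +X (signed
    toward the first-listed marker, conventionally the rostral-most); +Z is
    the direction orthogonal to X closest to ``dorsal_hint``; +Y completes a
    right-handed set (left-lateral for a fish in standard pose).

    Returns ``(axes, centroid)`` where ``axes`` rows are the X, Y, Z unit
    vectors expressed in the reference coordinate system.
    """
    ref = np.asarray(reference, dtype=float)
    c = ref.mean(axis=0)
    centered = ref - c
    _, _, Vt = np.linalg.svd(centered, full_matrices=True)
    x = Vt[0]
    if x @ centered[0] < 0:
        x = -x
    d = np.asarray(dorsal_hint, dtype=float)
    z = d - (d @ x) * x
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise ValueError("dorsal_hint is parallel to the principal body axis")
    z = z / nz
    y = np.cross(z, x)
    return np.stack([x, y, z]), c


def fit_body_plane(
    body: RigidBodyDef,
    trajectories: Mapping[str, MarkerTrajectory3D | np.ndarray],
    dorsal_hint: np.ndarray = (0.0, 0.0, 1.0),
) -> RigidBodyPose:
    """Fit the moving body-plane frame from >= 5 body markers.

    Same least-squares contract as :func:`fit_rigid_poses`, but the
    reference configuration is first re-expressed in its anatomical frame
    (see :func:`canonical_body_frame`), so the fitted pose directly gives
    the anatomical coordinate system (ACS) in world coordinates: +X rostral,
    +Y left-lateral, +Z dorsal.
    """
    if len(body.marker_ids) < 5:
        raise ValueError("the body plane requires >= 5 markers")
    axes, c = canonical_body_frame(body.reference, dorsal_hint)
    canon_ref = (body.reference - c) @ axes.T
    canon = RigidBodyDef(
        body_id=body.body_id, marker_ids=body.marker_ids, reference=canon_ref
    )
    return fit_rigid_poses(canon, trajectories)


def _as_xyz(tr: MarkerTrajectory3D | np.ndarray) -> np.ndarray:
    return tr.xyz if isinstance(tr, MarkerTrajectory3D) else np.asarray(tr, dtype=float)


def pairwise_distance_precision(
    trajectories: Mapping[str, MarkerTrajectory3D | np.ndarray],
    marker_ids: Sequence[str] | None = None,
    exclude_filled: bool = True,
) -> PrecisionReport:
    """Precision as SD of within-body pairwise marker distances.

    For every marker pair the 3D distance time series is computed over the
    frames where both markers are present; its standard deviation (ddof=1)
    estimates tracking precision, since true rigid-body distances are
    constant.  Frames filled by interpolation are excluded by default —
    interpolation artificially deflates the SD.

    Raises
    ------
    ValueError
        If no pair has at least two jointly visible frames.
    """
    ids = list(marker_ids) if marker_ids is not None else sorted(trajectories)
    if len(ids) < 2:
        raise ValueError("need at least two markers")
    pair_ids: list[tuple[str, str]] = []
    sds: list[float] = []
    excluded: list[tuple[str, str]] = []
    for a, b in combinations(ids, 2):
        xa, xb = _as_xyz(trajectories[a]), _as_xyz(trajectories[b])
        ok = np.all(np.isfinite(xa), axis=1) & np.all(np.isfinite(xb), axis=1)
        if exclude_filled:
            for tr in (trajectories[a], trajectories[b]):
                if isinstance(tr, MarkerTrajectory3D) and tr.filled is not None:
                    ok &= ~tr.filled
        if ok.sum() < 2:
            excluded.append((a, b))
            continue
        d = np.linalg.norm(xa[ok] - xb[ok], axis=1)
        pair_ids.append((a, b))
        sds.append(float(np.std(d, ddof=1)))
    if not pair_ids:
        raise ValueError("no marker pair with >= 2 jointly visible frames")
    sd_arr = np.asarray(sds)
    return PrecisionReport(
        pair_ids=pair_ids,
        pair_sd=sd_arr,
        mean_sd=float(sd_arr.mean()),
        n_pairs=len(pair_ids),
        excluded_pairs=excluded,
    )


def fill_gaps(traj: MarkerTrajectory3D, max_gap: int) -> MarkerTrajectory3D:
    """Fill short interior gaps by per-coordinate cubic interpolation.

    Gaps of at most ``max_gap`` consecutive missing frames bracketed by
    valid frames are filled with a cubic spline fitted to the valid frames;
    longer gaps and gaps touching either end of the trial stay missing.
    Filled frames are flagged in ``filled`` and carry NaN residuals.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    valid = ~traj.missing
    if max_gap == 0 or valid.all() or valid.sum() < 2:
        return traj
    T = traj.n_frames
    idx = np.arange(T)
    fillable = np.zeros(T, dtype=bool)
    f = 0
    while f < T:
        if valid[f]:
            f += 1
            continue
        start = f
        while f < T and not valid[f]:
            f += 1
        end = f  # gap is [start, end)
        interior = start > 0 and end < T
        if interior and (end - start) <= max_gap:
            fillable[start:end] = True
    if not fillable.any():
        return traj
    xyz = traj.xyz.copy()
    for k in range(3):
        spline = CubicSpline(idx[valid], traj.xyz[valid, k])
        xyz[fillable, k] = spline(idx[fillable])
    return MarkerTrajectory3D(
        marker_id=traj.marker_id,
        xyz=xyz,
        residual=traj.residual.copy(),
        missing=traj.missing & ~fillable,
        low_confidence=traj.low_confidence.copy(),
        filled=traj.filled | fillable,
    )
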