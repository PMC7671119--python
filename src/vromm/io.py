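"""CSV / YAML readers and writers for the pipeline's file dialects.

Formats:

* 2D points CSV — one file per camera, header ``<marker>_<cam>_x,
  <marker>_<cam>_y``, one row per frame, blank cell = missing.  The frame
  rate travels in a sidecar YAML.  Camera ids must not contain
  underscores; marker names may.
* DLT coefficients CSV — 11 rows by n_cameras columns, no header, column
  order = camera order (the de-facto layout of XROMM/DLT tooling).
* 3D trajectories CSV — ``<marker>_X,<marker>_Y,<marker>_Z,<marker>_res``
  per frame; a leading ``#`` comment line declares units.
* Rigid-body definition CSV — columns ``marker,x,y,z`` (mm).
* Events CSV — columns ``event,frame,time_s``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cameras import CameraModel, MarkerTrajectory3D
from .kinematics import EventTable
from .rigid_body import RigidBodyDef

__all__ = [
    "write_points2d_csv",
    "read_points2d_csv",
    "write_dlt_csv",
    "read_dlt_csv",
    "write_trajectories3d_csv",
    "read_trajectories3d_csv",
    "write_events_csv",
    "read_events_csv",
    "write_body_def_csv",
    "read_body_def_csv",
    "write_yaml",
    "read_yaml",
]


def write_points2d_csv(
    path: str | Path, cam_id: str, tracks: Mapping[str, np.ndarray]
) -> None:
    """Write one camera's 2D marker tracks; NaN becomes a blank cell."""
    if "_" in cam_id:
        raise ValueError(f"camera id {cam_id!r} must not contain underscores")
    markers = list(tracks)
    lengths = {len(tracks[m]) for m in markers}
    if len(lengths) != 1:
        raise ValueError("all tracks must share the frame count")
    (T,) = lengths
    header = []
    for m in markers:
        header += [f"{m}_{cam_id}_x", f"{m}_{cam_id}_y"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for f in range(T):
            row = []
            for m in markers:
                u, v = tracks[m][f]
                row += ["" if not np.isfinite(u) else repr(float(u)),
                        "" if not np.isfinite(v) else repr(float(v))]
            w.writerow(row)


def read_points2d_csv(*paths: str | Path) -> dict[str, dict[str, np.ndarray]]:
    """Read one or more 2D points CSVs into ``{cam_id: {marker: (T, 2)}}``."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for path in paths:
        df = pd.read_csv(path)
        cols: dict[tuple[str, str], dict[str, np.ndarray]] = {}
        for col in df.columns:
            parts = col.rsplit("_", 2)
            if len(parts) != 3 or parts[2] not in ("x", "y"):
                raise ValueError(
                    f"{path}: column {col!r} is not <marker>_<cam>_x/y"
                )
            marker, cam, axis = parts
            cols.setdefault((cam, marker), {})[axis] = df[col].to_numpy(float)
        for (cam, marker), axes in cols.items():
            if set(axes) != {"x", "y"}:
                raise ValueError(f"{path}: marker {marker!r} missing x or y column")
            out.setdefault(cam, {})[marker] = np.stack(
                [axes["x"], axes["y"]], axis=1
            )
    return out


def write_dlt_csv(path: str | Path, cameras: Sequence[CameraModel]) -> None:
    """11 rows x n_cameras columns of DLT coefficients, no header."""
    arr = np.stack([c.dlt for c in cameras], axis=1)
    np.savetxt(path, arr, delimiter=",", fmt="%.17g")


def read_dlt_csv(
    path: str | Path,
    cam_ids: Sequence[str] | None = None,
    image_size: tuple[int, int] = (1024, 1024),
) -> list[CameraModel]:
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    if arr.shape[0] != 11:
        raise ValueError(f"{path}: expected 11 coefficient rows, got {arr.shape[0]}")
    n = arr.shape[1]
    ids = list(cam_ids) if cam_ids is not None else [f"cam{i+1}" for i in range(n)]
    if len(ids) != n:
        raise ValueError("cam_ids must match the number of coefficient columns")
    return [
        CameraModel(dlt=arr[:, i], image_size=image_size, id=ids[i])
        for i in range(n)
    ]


def write_trajectories3d_csv(
    path: str | Path, trajectories: Mapping[str, MarkerTrajectory3D]
) -> None:
    cols = {}
    for m, tr in trajectories.items():
        cols[f"{m}_X"] = tr.xyz[:, 0]
        cols[f"{m}_Y"] = tr.xyz[:, 1]
        cols[f"{m}_Z"] = tr.xyz[:, 2]
        cols[f"{m}_res"] = tr.residual
    df = pd.DataFrame(cols)
    with open(path, "w", newline="") as fh:
        fh.write("# units: X,Y,Z in mm; res = RMS reprojection residual in px\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_trajectories3d_csv(path: str | Path) -> dict[str, MarkerTrajectory3D]:
    df = pd.read_csv(path, comment="#")
    markers: dict[str, dict[str, np.ndarray]] = {}
    for col in df.columns:
        marker, part = col.rsplit("_", 1)
        markers.setdefault(marker, {})[part] = df[col].to_numpy(float)
    out = {}
    for m, parts in markers.items():
        xyz = np.stack([parts["X"], parts["Y"], parts["Z"]], axis=1)
        out[m] = MarkerTrajectory3D(
            marker_id=m, xyz=xyz, residual=parts.get("res", np.full(len(xyz), np.nan))
        )
    return out


def write_events_csv(path: str | Path, events: EventTable) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["event", "frame", "time_s"])
        for name, (frame, time_s) in events.events.items():
            w.writerow([name, frame, repr(float(time_s))])


def read_events_csv(path: str | Path) -> EventTable:
    df = pd.read_csv(path)
    required = {"event", "frame", "time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: events CSV needs columns {sorted(required)}")
    return EventTable(
        events={
            str(r.event): (int(r.frame), float(r.time_s)) for r in df.itertuples()
        }
    )


def write_body_def_csv(path: str | Path, body: RigidBodyDef) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("# units: x,y,z in mm\n")
        w = csv.writer(fh)
        w.writerow(["marker", "x", "y", "z"])
        for m, (x, y, z) in zip(body.marker_ids, body.reference):
            w.writerow([m, repr(float(x)), repr(float(y)), repr(float(z))])


def read_body_def_csv(path: str | Path, body_id: str) -> RigidBodyDef:
    df = pd.read_csv(path, comment="#")
    return RigidBodyDef(
        body_id=body_id,
        marker_ids=[str(m) for m in df["marker"]],
        reference=df[["x", "y", "z"]].to_numpy(float),
    )


def write_yaml(path: str | Path, data: Mapping) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=False)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
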