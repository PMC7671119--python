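"""Synthetic suction-feeding strikes with known ground truth.

The generator builds an idealized striped-surfperch-like marker scene — a
rigid neurocranium carrying four markers, a five-marker body reference
plane, single urohyal / cleithrum / postcleithrum / epaxial markers and a
jaw-marker pair — and animates a unimodal strike: neurocranial elevation
about the body-plane Y axis, urohyal and cleithrum retraction/depression
along the body-plane axes (urohyal excursions exceed cleithrum excursions,
as observed in suction feeding), and sternohyoideus/epaxial shortening
peaking a configurable lag after peak gape.  Every kinematic variable
follows a raised-cosine pulse, so peak values and peak times are known in
closed form.

Skin slip — the imperfect mechanical coupling between skin-mounted markers
and the underlying muscle — is modelled as a pure multiplicative strain
attenuation: external length obeys

    L_ext(t) = L_i * (1 - alpha * s_int(t) / 100)

with internal strain ``s_int`` and coupling factor ``alpha`` in (0, 1].
The scene is then rendered through a 2-3 camera DLT rig with Gaussian
pixel noise, giving every downstream stage of the pipeline an input whose
correct answer is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cameras import CameraModel, project
from .kinematics import EventTable
from .rigid_body import RigidBodyDef, canonical_body_frame

__all__ = [
    "StrikeParams",
    "GroundTruth",
    "simulate_strike",
    "make_camera_rig",
    "render_observations",
    "raised_cosine",
]

NEURO_MARKERS = ("neuro1", "neuro2", "neuro3", "neuro4")
BODY_MARKERS = ("body1", "body2", "body3", "body4", "body5")

#: default marker-role map consumed by the pipeline
DEFAULT_ROLE_MAP = {
    "neurocranium": list(NEURO_MARKERS),
    "body_plane": list(BODY_MARKERS),
    "urohyal": "urohyal",
    "cleithrum": "cleithrum",
    "muscles": {
        "sh": ["urohyal", "postcleithrum"],
        "epaxial": ["neuro4", "epaxial"],
    },
    "jaw_pair": ["jaw_upper", "jaw_lower"],
}


@dataclass(frozen=True)
class StrikeParams:
    """Parameters of one synthetic strike.

    Units: times in s, lengths in mm, angles in degrees, strains in % of
    initial length, pixel noise in px.  Defaults emulate a ~20 cm surfperch
    suction strike filmed at 500 fps: peak sternohyoideus strain 7.2% and
    epaxial strain 3.9% of initial length, muscle shortening peaking 15 ms
    after peak gape, urohyal excursions exceeding cleithrum excursions, and
    a skin-slip coupling of 0.90 for both muscles.
    """

    frame_rate: float = 500.0
    duration: float = 0.2
    t_peak_gape: float = 0.1
    elevation_amp: float = 8.0
    urohyal_retraction_amp: float = 2.5
    urohyal_depression_amp: float = 3.5
    cleithrum_retraction_amp: float = 1.5
    cleithrum_depression_amp: float = 1.0
    sh_peak_strain: float = 7.2
    epax_peak_strain: float = 3.9
    strain_peak_lag: float = 0.015
    L_i_sh: float = 15.0
    L_i_epax: float = 12.0
    skin_slip_alpha: float = 0.90
    pixel_noise_sd: float = 0.3
    gape_amp: float = 6.0
    gape_base: float = 4.0
    kinematic_pulse_width: float = 0.08
    strain_pulse_width: float = 0.046
    seed: int = 0

    def __post_init__(self) -> None:
        def _positive(name: str) -> None:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v!r}")

        def _nonneg(name: str) -> None:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be non-negative and finite, got {v!r}")

        for name in (
            "frame_rate",
            "duration",
            "L_i_sh",
            "L_i_epax",
            "gape_base",
            "kinematic_pulse_width",
            "strain_pulse_width",
        ):
            _positive(name)
        for name in (
            "elevation_amp",
            "urohyal_retraction_amp",
            "urohyal_depression_amp",
            "cleithrum_retraction_amp",
            "cleithrum_depression_amp",
            "sh_peak_strain",
            "epax_peak_strain",
            "pixel_noise_sd",
            "gape_amp",
        ):
            _nonneg(name)
        if not (0 < self.t_peak_gape < self.duration):
            raise ValueError(
                f"t_peak_gape must lie inside (0, duration), got {self.t_peak_gape!r}"
            )
        if not (0 < self.skin_slip_alpha <= 1):
            raise ValueError(
                f"skin_slip_alpha must lie in (0, 1], got {self.skin_slip_alpha!r}"
            )
        if not np.isfinite(self.strain_peak_lag):
            raise ValueError("strain_peak_lag must be finite")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class GroundTruth:
    """Everything the generator knows about one strike."""

    params: StrikeParams
    t: np.ndarray  # (T,) s
    markers: dict[str, np.ndarray]  # name -> (T, 3) mm, world frame
    body_def: RigidBodyDef
    neuro_def: RigidBodyDef
    body_axes: np.ndarray  # (3, 3) ACS axes (rows X, Y, Z) in world coords
    neuro_rotation: np.ndarray  # (T, 3, 3) true neurocranium rotation
    elevation_deg: np.ndarray  # (T,)
    excursions: dict[str, dict[str, np.ndarray]]  # marker -> retraction/depression
    internal_length: dict[str, np.ndarray]  # muscle -> (T,) mm
    external_length: dict[str, np.ndarray]
    internal_strain: dict[str, np.ndarray]  # % of L_i, shortening positive
    external_strain: dict[str, np.ndarray]
    events: EventTable
    role_map: dict = field(default_factory=lambda: dict(DEFAULT_ROLE_MAP))

    @property
    def frame_rate(self) -> float:
        return self.params.frame_rate

    @property
    def marker_names(self) -> list[str]:
        return list(self.markers)


def raised_cosine(t: np.ndarray, t_center: float, width: float) -> np.ndarray:
    """Unimodal raised-cosine pulse: 0 outside, 1 at ``t_center``.

    Supported on ``[t_center - width/2, t_center + width/2]``; smooth (C1)
    at the edges, with an analytic peak location and derivative.
    """
    x = (np.asarray(t, dtype=float) - t_center) / width
    g = 0.5 * (1.0 + np.cos(2.0 * np.pi * x))
    return np.where(np.abs(x) <= 0.5, g, 0.0)


def raised_cosine_derivative(t: np.ndarray, t_center: float, width: float) -> np.ndarray:
    """Closed-form time derivative of :func:`raised_cosine` (per second)."""
    x = (np.asarray(t, dtype=float) - t_center) / width
    dg = -(np.pi / width) * np.sin(2.0 * np.pi * x)
    return np.where(np.abs(x) <= 0.5, dg, 0.0)


# Reference marker layout, mm, world frame: +X rostral, +Y left, +Z dorsal.
# Loosely anatomical for a ~20 cm fish; head near +X, body trailing to -X.
_NEURO_REF = np.array(
    [
        [32.0, 0.0, 14.0],  # rostral-dorsal
        [24.0, 6.0, 16.0],  # left
        [24.0, -6.0, 16.0],  # right
        [14.0, 0.0, 19.0],  # most caudal (supraoccipital): epaxial attachment
    ]
)
_BODY_REF = np.array(
    [
        [-5.0, 3.0, 2.0],  # rostral-most body marker, listed first
        [-20.0, 3.5, 8.0],
        [-35.0, 3.0, -4.0],
        [-50.0, 2.5, 6.0],
        [-65.0, 3.0, 0.0],
    ]
)
_URO_REF = np.array([12.0, 0.0, -10.0])
_CLEI_REF = np.array([5.0, 0.0, -8.0])
_JAW_UPPER = np.array([36.0, 0.0, 4.0])
_PIVOT = np.array([10.0, 0.0, 8.0])  # neurocranial rotation pivot
_SH_DIR = np.array([-1.0, 0.0, 0.15])  # urohyal -> postcleithrum
_EPAX_DIR = np.array([-1.0, 0.0, -0.12])  # caudal neuro marker -> epaxial


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _axis_rotation(axis: np.ndarray, angles_rad: np.ndarray) -> np.ndarray:
    """Rotation matrices about a fixed unit axis (Rodrigues), batched."""
    k = _unit(np.asarray(axis, dtype=float))
    K = np.array(
        [[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]]
    )
    a = np.asarray(angles_rad, dtype=float)[:, None, None]
    eye = np.eye(3)
    return eye + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def simulate_strike(params: StrikeParams | None = None) -> GroundTruth:
    """Generate one strike's ground-truth poses, markers, lengths and events.

    Deterministic: the same parameters always give bit-identical output
    (randomness enters only when observations are rendered).
    """
    p = params if params is not None else StrikeParams()
    T = p.n_frames
    t = np.arange(T) / p.frame_rate

    g_kin = raised_cosine(t, p.t_peak_gape, p.kinematic_pulse_width)
    t_strain_peak = p.t_peak_gape + p.strain_peak_lag
    g_strain = raised_cosine(t, t_strain_peak, p.strain_pulse_width)

    body_def = RigidBodyDef("body_plane", list(BODY_MARKERS), _BODY_REF)
    neuro_def = RigidBodyDef("neurocranium", list(NEURO_MARKERS), _NEURO_REF)
    axes, _ = canonical_body_frame(_BODY_REF)  # rows: X (rostral), Y, Z (dorsal)
    x_acs, y_acs, z_acs = axes

    markers: dict[str, np.ndarray] = {}
    for name, ref in zip(BODY_MARKERS, _BODY_REF):
        markers[name] = np.tile(ref, (T, 1))

    # neurocranium: elevation about the body-plane Y axis through the pivot
    elev_deg = p.elevation_amp * g_kin
    R_neuro = _axis_rotation(y_acs, np.deg2rad(elev_deg))
    for name, ref in zip(NEURO_MARKERS, _NEURO_REF):
        markers[name] = _PIVOT + np.einsum("fij,j->fi", R_neuro, ref - _PIVOT)

    # urohyal / cleithrum: retraction (-X_acs) and depression (-Z_acs)
    excursions: dict[str, dict[str, np.ndarray]] = {}
    for name, ref, r_amp, d_amp in (
        ("urohyal", _URO_REF, p.urohyal_retraction_amp, p.urohyal_depression_amp),
        ("cleithrum", _CLEI_REF, p.cleithrum_retraction_amp, p.cleithrum_depression_amp),
    ):
        retraction = r_amp * g_kin
        depression = d_amp * g_kin
        markers[name] = (
            ref
            - retraction[:, None] * x_acs
            - depression[:, None] * z_acs
        )
        excursions[name] = {"retraction": retraction, "depression": depression}

    # muscles: internal strain follows the strain pulse; the external
    # (skin-marker) length is the skin-slip-attenuated version by construction
    internal_strain = {
        "sh": p.sh_peak_strain * g_strain,
        "epaxial": p.epax_peak_strain * g_strain,
    }
    external_strain = {
        m: p.skin_slip_alpha * s for m, s in internal_strain.items()
    }
    L_i = {"sh": p.L_i_sh, "epaxial": p.L_i_epax}
    internal_length = {m: L_i[m] * (1 - internal_strain[m] / 100.0) for m in L_i}
    external_length = {m: L_i[m] * (1 - external_strain[m] / 100.0) for m in L_i}

    sh_dir = _unit(_SH_DIR)
    markers["postcleithrum"] = (
        markers["urohyal"] + external_length["sh"][:, None] * sh_dir
    )
    ep_dir = _unit(_EPAX_DIR)
    markers["epaxial"] = (
        markers["neuro4"] + external_length["epaxial"][:, None] * ep_dir
    )

    # jaw pair: distance peaks exactly at peak gape
    gape = p.gape_base + p.gape_amp * g_kin
    markers["jaw_upper"] = np.tile(_JAW_UPPER, (T, 1))
    markers["jaw_lower"] = _JAW_UPPER - gape[:, None] * z_acs

    f_pg = int(round(p.t_peak_gape * p.frame_rate))
    events = EventTable(events={"peak_gape": (f_pg, f_pg / p.frame_rate)})

    return GroundTruth(
        params=p,
        t=t,
        markers=markers,
        body_def=body_def,
        neuro_def=neuro_def,
        body_axes=axes,
        neuro_rotation=R_neuro,
        elevation_deg=elev_deg,
        excursions=excursions,
        internal_length=internal_length,
        external_length=external_length,
        internal_strain=internal_strain,
        external_strain=external_strain,
        events=events,
    )


def make_camera_rig(
    n_cameras: int = 2,
    geometry: Mapping | None = None,
) -> list[CameraModel]:
    """Build a 2- or 3-camera DLT rig viewing the working volume.

    The default geometry mimics a feeding-tank setup filmed on 1024x1024 px
    sensors: two cameras at oblique +/-35 deg azimuths about the lateral
    viewing axis, and an optional third camera viewing the tank
    perpendicularly (straight from the side).  ``geometry`` may override
    ``distance_mm``, ``focal_px``, ``target``, ``azimuths_deg``,
    ``elevations_deg`` and ``image_size``.

    Any two cameras' rays to the scene centre subtend more than 10 degrees;
    degenerate requests (coincident centres, n outside {2, 3}) are
    rejected.
    """
    if n_cameras not in (2, 3):
        raise ValueError(f"n_cameras must be 2 or 3, got {n_cameras!r}")
    geo = dict(geometry or {})
    distance = float(geo.get("distance_mm", 650.0))
    focal = float(geo.get("focal_px", 3500.0))
    target = np.asarray(geo.get("target", (0.0, 0.0, 5.0)), dtype=float)
    image_size = tuple(geo.get("image_size", (1024, 1024)))
    azimuths = list(geo.get("azimuths_deg", (35.0, -35.0, 0.0)))[:n_cameras]
    elevations = list(geo.get("elevations_deg", (15.0, 15.0, 0.0)))[:n_cameras]

    centers = []
    for az, el in zip(azimuths, elevations):
        a, e = np.deg2rad(az), np.deg2rad(el)
        # cameras sit on the fish's left (+Y) side of the tank
        d = np.array([np.cos(e) * np.sin(a), np.cos(e) * np.cos(a), np.sin(e)])
        centers.append(target + distance * d)
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            ri = _unit(centers[i] - target)
            rj = _unit(centers[j] - target)
            ang = np.degrees(np.arccos(np.clip(ri @ rj, -1, 1)))
            if ang < 1e-6:
                raise ValueError("degenerate rig: coincident camera centres")
            if ang <= 10.0:
                raise ValueError(
                    f"cameras {i} and {j} subtend only {ang:.1f} deg at the "
                    "scene centre; need > 10 deg for stable triangulation"
                )

    cams = []
    for i, C in enumerate(centers):
        cams.append(
            _pinhole_dlt(C, target, focal, image_size, cam_id=f"cam{i + 1}")
        )
    return cams


def _pinhole_dlt(
    center: np.ndarray,
    target: np.ndarray,
    focal_px: float,
    image_size: tuple[int, int],
    cam_id: str,
) -> CameraModel:
    """DLT coefficients of an ideal pinhole camera looking at ``target``."""
    fwd = _unit(target - center)
    up = np.array([0.0, 0.0, 1.0])
    if abs(fwd @ up) > 0.99:
        up = np.array([0.0, 1.0, 0.0])
    right = _unit(np.cross(fwd, up))
    down = np.cross(fwd, right)
    R = np.stack([right, down, fwd])
    cx, cy = image_size[0] / 2.0, image_size[1] / 2.0
    K = np.array([[focal_px, 0.0, cx], [0.0, focal_px, cy], [0.0, 0.0, 1.0]])
    P = K @ np.hstack([R, (-R @ center)[:, None]])
    if abs(P[2, 3]) < 1e-9:
        raise ValueError("camera centre passes through the world origin plane")
    P = P / P[2, 3]
    return CameraModel(dlt=P.flatten()[:11], image_size=image_size, id=cam_id)


def render_observations(
    truth: GroundTruth,
    rig: list[CameraModel],
    pixel_noise_sd: float | None = None,
    seed: int | None = None,
    dropout_rate: float = 0.0,
) -> dict[str, dict[str, np.ndarray]]:
    """Project ground-truth markers into each camera and add pixel noise.

    Observations are the exact DLT projection plus iid Gaussian noise of
    standard deviation ``pixel_noise_sd`` on each coordinate (defaults to
    the strike parameters' value).  Points behind a camera are flagged
    missing (NaN) rather than silently projected; ``dropout_rate`` injects
    additional missing frames at random.  Deterministic given the seed.

    Returns ``obs[camera_id][marker_id]`` as ``(T, 2)`` pixel tracks.
    """
    if pixel_noise_sd is None:
        pixel_noise_sd = truth.params.pixel_noise_sd
    if pixel_noise_sd < 0:
        raise ValueError("pixel_noise_sd must be non-negative")
    if not (0 <= dropout_rate < 1):
        raise ValueError("dropout_rate must lie in [0, 1)")
    rng = np.random.default_rng(truth.params.seed if seed is None else seed)

    out: dict[str, dict[str, np.ndarray]] = {}
    for cam in rig:
        cam_obs: dict[str, np.ndarray] = {}
        L = cam.dlt
        for name in truth.marker_names:
            xyz = truth.markers[name]
            w = xyz @ L[8:11] + 1.0
            uv = np.full((len(xyz), 2), np.nan)
            front = w > 1e-9
            if front.any():
                uv[front] = project(cam, xyz[front])
            if pixel_noise_sd > 0:
                uv = uv + rng.normal(0.0, pixel_noise_sd, size=uv.shape)
            if dropout_rate > 0:
                drop = rng.random(len(uv)) < dropout_rate
                uv[drop] = np.nan
            cam_obs[name] = uv
        out[cam.id] = cam_obs
    return out
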