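"""Fully known synthetic inputs for every pipeline stage.

The centerpiece is a floating-base hexapod whose topology mirrors the ant
locomotor system: thorax (free 6-DOF base), head (ball), petiole (hinge),
abdomen/gaster (ball), and six legs with a ball thorax/coxa joint, a ball
(front) or hinge (middle/rear) coxa/trochanter joint, then hinge
trochanter/femur, femur/tibia, tibia/metatarsus and metatarsus/tarsus joints
— 40 segments and 65 DOFs, two markers per segment.  Joint placement frames
are constructed with the same sagittal-plane/medial-axis conventions as the
real model and each joint records the geometric primitives (ball center or
condyle pair) it was built from, so Monte Carlo joint perturbations can
rebuild the frames.  Range-of-motion limits default to the published
per-joint allowable spans, centered on the neutral pose.

Default dimensions give a ~6.6 mm body so that millimetre-scale
perturbation radii are proportionate.  Gait trajectories are smooth sums of
sines within ROM, opposite tripods in antiphase, with the base advancing at
a constant mean speed; a trial is rendered through forward kinematics with
optional isotropic marker noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .geometry import (FrameDef, PlaneDef, build_ball_frame, build_thorax_frame,
                       hinge_frame_from_centers)
from .model import KinematicModel, SegmentSpec, JointSpec, assemble_model, check_rom
from .trial import MarkerTrial

__all__ = [
    "TRUNK_ROM_DEG",
    "LEG_ROM_DEG",
    "SyntheticGaitSpec",
    "SurfaceCloudSpec",
    "make_synthetic_hexapod",
    "make_gait_trajectories",
    "render_marker_trial",
    "make_articular_surface",
]

# Maximum allowable range of motion (deg) of the trunk joints.
TRUNK_ROM_DEG = {
    "head": {"abduction": 75.0, "internal_rotation": 40.0, "flexion": 120.0},
    "abdomen": {"abduction": 25.0, "internal_rotation": 60.0, "flexion": 100.0},
}

# Maximum allowable range of motion (deg) of the leg joints per leg row;
# None marks a blocked DOF (middle/rear coxa/trochanter reduce to a hinge).
LEG_ROM_DEG = {
    "cox": {
        "abduction": {"front": 70.0, "middle": 80.0, "rear": 110.0},
        "internal_rotation": {"front": 40.0, "middle": 55.0, "rear": 105.0},
        "flexion": {"front": 80.0, "middle": 100.0, "rear": 105.0},
    },
    "tro": {
        "abduction": {"front": 120.0, "middle": None, "rear": None},
        "internal_rotation": {"front": 165.0, "middle": None, "rear": None},
        "flexion": {"front": 180.0, "middle": 120.0, "rear": 130.0},
    },
    "fe": {"flexion": {"front": 130.0, "middle": 180.0, "rear": 120.0}},
    "ti": {"flexion": {"front": 160.0, "middle": 165.0, "rear": 190.0}},
    "mt": {"flexion": {"front": 190.0, "middle": 200.0, "rear": 175.0}},
    "ta": {"flexion": {"front": 200.0, "middle": 200.0, "rear": 240.0}},
}

_ROWS = {"f": "front", "m": "middle", "r": "rear"}
# Tripod A legs move in phase; tripod B in antiphase.
_TRIPOD_A = ("fl", "mr", "rl")

# Neutral-pose layout constants (mm); anterior is -x, up is +z, left is +y.
_P_H = np.array([-1.5, 0.0, 2.0])  # thorax/head ball center
_P_A = np.array([1.0, 0.0, 2.0])  # petiole articulation on the thorax
_ABD_CENTER = np.array([1.6, 0.0, 1.95])
# Half the condyle separation; the full 0.4 mm separation matches the
# leg-joint width (~ leg diameter) of a ~6.6 mm ant.
_CONDYLE_HALF_SEP = 0.2
_LEG_X = {"front": -1.2, "middle": -0.2, "rear": 0.8}
_LEG_SPLAY_DEG = {"front": 25.0, "middle": 5.0, "rear": -20.0}
# (along-leg distance, height offset) of successive joints from the coxa center
_LEG_STATIONS = [("tro", 0.5, -0.35), ("fe", 0.85, -0.45), ("ti", 2.0, 0.4),
                 ("mt", 3.0, -1.0), ("ta", 3.5, -1.55)]
_LEG_TIP = (3.9, -1.85)
# Hinge-axis twist (deg) about the leg direction per joint: successive leg
# joints do not share one rotation plane, which is what makes the chain
# well-conditioned for IK (parallel axes would be mutually redundant).
_AXIS_TWIST_DEG = {"tro": 30.0, "fe": -20.0, "ti": 15.0, "mt": -15.0, "ta": 10.0}


def _centered_rom(spans: dict) -> dict:
    return {dof: (-s / 2.0, s / 2.0) for dof, s in spans.items() if s is not None}


def _local_frame(parent_world: FrameDef, world: FrameDef) -> FrameDef:
    R = parent_world.rotation.T @ world.rotation
    o = parent_world.rotation.T @ (world.origin - parent_world.origin)
    return FrameDef(origin=o, rotation=R)


def _to_local(parent_world: FrameDef, p: np.ndarray) -> np.ndarray:
    return parent_world.rotation.T @ (np.asarray(p, dtype=float) - parent_world.origin)


def _plane_local(parent_world: FrameDef, plane: PlaneDef) -> dict:
    return {
        "sagittal_normal": parent_world.rotation.T @ plane.unit_normal,
        "sagittal_point": _to_local(parent_world, plane.point_on_plane),
    }


def _seg_markers(p0: np.ndarray, p1: np.ndarray, frame: FrameDef, prefix: str,
                 offset: float = 0.12) -> dict:
    """Two markers along a segment, offset off-axis in two different directions."""
    axis = p1 - p0
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u1 = np.cross(axis, ref)
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(axis, u1)
    m_a = p0 + 0.3 * (p1 - p0) + offset * u1
    m_b = p0 + 0.85 * (p1 - p0) + offset * u2
    return {f"{prefix}_a": _to_local(frame, m_a), f"{prefix}_b": _to_local(frame, m_b)}


def make_synthetic_hexapod(petiole_rom_deg: float = 60.0, scale: float = 1.0,
                           flip_x: bool = False) -> KinematicModel:
    """Build the reference synthetic ant model (40 segments, 65 DOF).

    ``petiole_rom_deg`` is the allowable flexion span of the petiole hinge
    (not published for the real animal); ``scale`` uniformly scales the
    neutral geometry; ``flip_x`` mirrors the lateral-axis sign convention of
    the constructed frames.
    """
    if scale <= 0:
        raise InvalidInputError("scale must be positive")
    s = scale
    plane = PlaneDef(unit_normal=np.array([0.0, 1.0, 0.0]), point_on_plane=s * _P_A)
    thorax_w = build_thorax_frame(s * _P_H, s * _P_A, plane, flip_x=flip_x)
    segments = []

    # floating base: thorax placed in the ground frame
    base = JointSpec(name="base", joint_type="free6", frame_in_parent=thorax_w)
    th_markers = {
        "th_a": _to_local(thorax_w, s * np.array([-1.0, 0.3, 2.3])),
        "th_b": _to_local(thorax_w, s * np.array([0.5, -0.3, 2.25])),
    }
    segments.append(SegmentSpec(name="thorax", parent="ground", joint=base, markers=th_markers))

    def geom_ball(center_w, prev_w):
        return {"kind": "ball", "center": _to_local(thorax_w, center_w),
                "prev_origin": _to_local(thorax_w, prev_w),
                "flip_x": flip_x, **_plane_local(thorax_w, plane)}

    # head
    head_w = build_ball_frame(s * _P_H, thorax_w.origin, plane, flip_x=flip_x)
    head_markers = _seg_markers(s * _P_H, s * np.array([-2.4, 0.0, 2.1]), head_w, "head",
                                offset=0.2 * s)
    segments.append(SegmentSpec(
        name="head", parent="thorax",
        joint=JointSpec(name="head", joint_type="ball3",
                        frame_in_parent=_local_frame(thorax_w, head_w),
                        rom_limits=_centered_rom(TRUNK_ROM_DEG["head"]),
                        geometry=geom_ball(s * _P_H, thorax_w.origin)),
        markers=head_markers))

    # petiole (hinge, lateral axis) and abdomen (ball)
    pet_a = s * (_P_A - np.array([0.0, _CONDYLE_HALF_SEP, 0.0]))
    pet_b = s * (_P_A + np.array([0.0, _CONDYLE_HALF_SEP, 0.0]))
    pet_w = hinge_frame_from_centers(pet_a, pet_b, thorax_w.origin, plane)
    segments.append(SegmentSpec(
        name="petiole", parent="thorax",
        joint=JointSpec(name="petiole", joint_type="hinge1",
                        frame_in_parent=_local_frame(thorax_w, pet_w),
                        rom_limits={"flexion": (-petiole_rom_deg / 2, petiole_rom_deg / 2)},
                        geometry={"kind": "hinge", "condyle_a": _to_local(thorax_w, pet_a),
                                  "condyle_b": _to_local(thorax_w, pet_b),
                                  "prev_origin": _to_local(thorax_w, thorax_w.origin),
                                  **_plane_local(thorax_w, plane)}),
        markers=_seg_markers(s * _P_A, s * _ABD_CENTER, pet_w, "pet", offset=0.1 * s)))

    abd_w = build_ball_frame(s * _ABD_CENTER, pet_w.origin, plane, flip_x=flip_x)
    segments.append(SegmentSpec(
        name="abdomen", parent="petiole",
        joint=JointSpec(name="abdomen", joint_type="ball3",
                        frame_in_parent=_local_frame(pet_w, abd_w),
                        rom_limits=_centered_rom(TRUNK_ROM_DEG["abdomen"]),
                        geometry={"kind": "ball", "center": _to_local(pet_w, s * _ABD_CENTER),
                                  "prev_origin": _to_local(pet_w, pet_w.origin),
                                  "flip_x": flip_x, **_plane_local(pet_w, plane)}),
        markers=_seg_markers(s * _ABD_CENTER, s * np.array([2.9, 0.0, 1.8]), abd_w, "abd",
                             offset=0.25 * s)))

    # legs
    for leg in ("fl", "fr", "ml", "mr", "rl", "rr"):
        row = _ROWS[leg[0]]
        lat = 1.0 if leg[1] == "l" else -1.0
        phi = np.deg2rad(_LEG_SPLAY_DEG[row])
        d = np.array([-np.sin(phi), lat * np.cos(phi), 0.0])
        a_dir = np.array([d[1], -d[0], 0.0])  # horizontal, perpendicular to the leg
        cox_center = s * np.array([_LEG_X[row], lat * 0.45, 1.85])

        def station(t, h):
            return cox_center + s * t * d + s * np.array([0.0, 0.0, h])

        pts = {name: station(t, h) for name, t, h in _LEG_STATIONS}
        tip = station(*_LEG_TIP)
        chain_pts = [cox_center] + [pts[n] for n, _, _ in _LEG_STATIONS] + [tip]

        def hinge_axis(token):
            # rotate the nominal perpendicular axis about the leg direction
            ang = np.deg2rad(_AXIS_TWIST_DEG[token])
            c, si = np.cos(ang), np.sin(ang)
            return c * a_dir + si * np.cross(d, a_dir) + (1 - c) * (d @ a_dir) * d

        # thorax/coxa ball joint
        cox_w = build_ball_frame(cox_center, thorax_w.origin, plane, flip_x=flip_x)
        rom = {dof: LEG_ROM_DEG["cox"][dof][row] for dof in LEG_ROM_DEG["cox"]}
        segments.append(SegmentSpec(
            name=f"{leg}_cox", parent="thorax",
            joint=JointSpec(name=f"{leg}_cox", joint_type="ball3",
                            frame_in_parent=_local_frame(thorax_w, cox_w),
                            rom_limits=_centered_rom(rom),
                            geometry=geom_ball(cox_center, thorax_w.origin)),
            markers=_seg_markers(cox_center, pts["tro"], cox_w, f"{leg}_cox", offset=0.2 * s)))

        prev_w = cox_w
        parent_name = f"{leg}_cox"
        for i, (token, _, _) in enumerate(_LEG_STATIONS):
            center = pts[token]
            nxt = chain_pts[i + 2]
            ball = token == "tro" and row == "front"
            rom = {dof: LEG_ROM_DEG[token][dof][row] for dof in LEG_ROM_DEG[token]
                   if LEG_ROM_DEG[token][dof][row] is not None}
            if ball:
                jw = build_ball_frame(center, prev_w.origin, plane, flip_x=flip_x)
                geometry = {"kind": "ball", "center": _to_local(prev_w, center),
                            "prev_origin": _to_local(prev_w, prev_w.origin),
                            "flip_x": flip_x, **_plane_local(prev_w, plane)}
                jtype = "ball3"
            else:
                ax = hinge_axis(token)
                ca = center - s * _CONDYLE_HALF_SEP * ax
                cb = center + s * _CONDYLE_HALF_SEP * ax
                jw = hinge_frame_from_centers(ca, cb, prev_w.origin, plane)
                geometry = {"kind": "hinge", "condyle_a": _to_local(prev_w, ca),
                            "condyle_b": _to_local(prev_w, cb),
                            "prev_origin": _to_local(prev_w, prev_w.origin),
                            **_plane_local(prev_w, plane)}
                jtype = "hinge1"
            name = f"{leg}_{token}"
            segments.append(SegmentSpec(
                name=name, parent=parent_name,
                joint=JointSpec(name=name, joint_type=jtype,
                                frame_in_parent=_local_frame(prev_w, jw),
                                rom_limits=_centered_rom(rom), geometry=geometry),
                markers=_seg_markers(center, nxt, jw, name, offset=0.2 * s)))
            prev_w = jw
            parent_name = name

    model = assemble_model(segments)
    assert model.n_dof == 65 and model.n_segments == 40
    return model


@dataclass
class SyntheticGaitSpec:
    """Smooth periodic gait within ROM.

    Per-DOF oscillations are sums of a fundamental at ``1/duration`` Hz and a
    second harmonic (30 % amplitude); amplitudes default to 35 % of each
    DOF's half-span, capped per joint class (degrees).  Opposite tripods are
    phase-shifted by pi.  The base advances at ``speed_mm_s`` opposite the
    global x-axis.  ``oscillations`` may override (amplitude_deg,
    frequency_hz, phase_rad) per coordinate name.
    """

    duration: float = 1.39
    rate: float = 100.0
    amplitude_fraction: float = 0.35
    amplitude_cap_deg: dict = field(default_factory=lambda: {
        "hinge": 15.0, "ball": 8.0, "trunk": 5.0})
    speed_mm_s: float = 3.4
    vertical_bob_mm: float = 0.1
    tripod_phase: float = np.pi
    oscillations: dict = field(default_factory=dict)
    noise: Optional[tuple] = None  # None | ("gaussian", sd_mm) | ("uniform_ball", r_mm)
    seed: int = 0

    def __post_init__(self):
        if self.duration * self.rate < 2:
            raise InvalidParameterError("duration x rate must cover at least 2 samples")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.rate))


_TRUNK_JOINTS = ("head", "petiole", "abdomen")


def _default_oscillation(model: KinematicModel, k: int, spec: SyntheticGaitSpec):
    jname, dof = model.coordinate_layout[k]
    half_span = float(np.rad2deg(model.upper_bounds[k] - model.lower_bounds[k])) / 2.0
    if jname in _TRUNK_JOINTS:
        cap = spec.amplitude_cap_deg["trunk"]
    elif model.joint(jname).joint_type == "hinge1":
        cap = spec.amplitude_cap_deg["hinge"]
    else:
        cap = spec.amplitude_cap_deg["ball"]
    amp = min(spec.amplitude_fraction * half_span, cap)
    leg = jname.split("_")[0]
    phase = 0.0 if (leg in _TRIPOD_A or jname in _TRUNK_JOINTS) else spec.tripod_phase
    # deterministic per-DOF phase offset so DOFs are not all synchronous
    phase += 0.7 * (k % 5)
    return amp, 1.0 / spec.duration, phase


def make_gait_trajectories(model: KinematicModel, spec: SyntheticGaitSpec):
    """Ground-truth pose time series (radians/mm).

    Returns ``(times, Q)`` with Q of shape (n_frames, n_dof).  Raises if any
    generated sample violates ROM.
    """
    n = spec.n_frames
    t = np.arange(n) / spec.rate
    Q = np.zeros((n, model.n_dof))
    base_R = model.segments[0].joint.frame_in_parent.rotation
    travel = np.outer(-spec.speed_mm_s * t, np.array([1.0, 0.0, 0.0]))
    travel[:, 2] += spec.vertical_bob_mm * np.sin(2 * np.pi * 2.0 / spec.duration * t)
    Q[:, :3] = travel @ base_R  # ground displacement expressed in base joint axes
    for k in range(model.n_dof):
        if k < 6:  # floating base handled above (rotations stay neutral)
            continue
        cname = model.coordinate_names[k]
        amp, freq, phase = spec.oscillations.get(cname, _default_oscillation(model, k, spec))
        w = 2 * np.pi * freq
        ang = amp * (np.sin(w * t + phase) + 0.3 * np.sin(2 * w * t + 1.3 * phase))
        Q[:, k] = np.deg2rad(ang)
    for f in range(n):
        violations = check_rom(model, Q[f])
        if violations:
            v = violations[0]
            raise InvalidParameterError(
                f"generated trajectory violates ROM at frame {f}: "
                f"{v.joint}:{v.dof} = {v.value_deg:.1f} deg, limits {v.limit_deg}")
    return t, Q


def render_marker_trial(model: KinematicModel, pose_series: np.ndarray,
                        noise: Optional[tuple] = None, seed: int = 0,
                        rate: float = 100.0) -> MarkerTrial:
    """Forward-kinematics marker trajectories plus optional isotropic noise.

    ``noise`` is None, ``("gaussian", sd_mm)`` (per-axis sd) or
    ``("uniform_ball", radius_mm)``.
    """
    Q = np.asarray(pose_series, dtype=float)
    n = Q.shape[0]
    data = np.empty((n, len(model.marker_names), 3))
    for f in range(n):
        data[f] = model.marker_positions_array(Q[f])
    if noise is not None:
        kind, mag = noise
        rng = np.random.default_rng(seed)
        if mag < 0:
            raise InvalidParameterError("noise magnitude must be >= 0")
        if kind == "gaussian":
            data = data + rng.normal(scale=mag, size=data.shape) if mag > 0 else data
        elif kind == "uniform_ball":
            from .montecarlo import sample_uniform_ball

            offsets = sample_uniform_ball(mag, rng, size=n * data.shape[1])
            data = data + offsets.reshape(data.shape)
        else:
            raise InvalidParameterError(f"unknown noise model {kind!r}")
    return MarkerTrial(marker_names=list(model.marker_names), data=data, rate=rate)


@dataclass(frozen=True)
class SurfaceCloudSpec:
    """Synthetic articular surface: a noisy spherical cap."""

    center: tuple = (0.0, 0.0, 0.0)
    radius: float = 0.35
    cap_half_angle_deg: float = 60.0
    n_points: int = 200
    radial_noise_sd: float = 0.0
    axis: tuple = (0.0, 0.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.radius <= 0:
            raise InvalidInputError("radius must be positive")
        if not 0 < self.cap_half_angle_deg <= 90:
            raise InvalidInputError("cap half-angle must lie in (0, 90] degrees")
        if self.n_points < 4:
            raise InvalidInputError("need at least 4 points")


def make_articular_surface(spec: SurfaceCloudSpec) -> np.ndarray:
    """Points uniform on a spherical cap with radial Gaussian noise, (n, 3) mm."""
    rng = np.random.default_rng(spec.seed)
    cos_cap = np.cos(np.deg2rad(spec.cap_half_angle_deg))
    cosu = rng.uniform(cos_cap, 1.0, spec.n_points)
    sinu = np.sqrt(1 - cosu**2)
    phi = rng.uniform(0, 2 * np.pi, spec.n_points)
    local = np.column_stack([sinu * np.cos(phi), sinu * np.sin(phi), cosu])
    axis = np.asarray(spec.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # rotate cap axis (+z) onto the requested axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(z @ axis)
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx / (1 + c)
    dirs = local @ R.T
    radii = np.full(spec.n_points, spec.radius)
    if spec.radial_noise_sd > 0:
        radii = radii + rng.normal(scale=spec.radial_noise_sd, size=spec.n_points)
    return np.asarray(spec.center, dtype=float) + dirs * radii[:, None]
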