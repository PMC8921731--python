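"""Articulated rigid-body model of the ant and its forward kinematics.

The locomotor system is represented as a tree of rigid segments connected by
typed joints: a 6-DOF free joint for the floating base (thorax), 3-DOF
ball-and-socket joints (e.g. thorax/head, thorax/coxa), 1-DOF hinges (e.g.
femur/tibia) and 0-DOF locked joints.  Each joint carries a placement frame
in the parent segment and (optionally) in the child segment, per-DOF range-of-
motion limits, and each segment carries virtual markers at anatomical
landmarks.

Rotation conventions follow the anatomical sign convention: abduction is a
positive rotation about the joint x-axis, internal rotation positive about y,
extension positive about z (flexion is therefore negative about z).  Ball
joints use the intrinsic x-y-z Euler sequence (abduction, internal rotation,
flexion).  Angles are radians internally; ROM limits are stated in degrees and
converted at the boundary.  Translations are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _fastkin
from .errors import InvalidInputError, InvalidTopologyError
from .geometry import FrameDef

__all__ = [
    "JOINT_DOF_NAMES",
    "JointSpec",
    "SegmentSpec",
    "KinematicModel",
    "FKResult",
    "RomViolation",
    "assemble_model",
    "forward_kinematics",
    "check_rom",
    "parse_marker_name",
]

GROUND = "ground"

# DOF names per joint type, in coordinate-layout order.
JOINT_DOF_NAMES = {
    "free6": ["tx", "ty", "tz", "rx", "ry", "rz"],
    "ball3": ["abduction", "internal_rotation", "flexion"],
    "hinge1": ["flexion"],
    "locked0": [],
}

# Default translation bounds for the floating base (mm): effectively free.
_FREE_TRANSLATION_LIMIT = 1.0e6

_LEG_PREFIXES = ("fl", "fr", "ml", "mr", "rl", "rr")


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@dataclass
class JointSpec:
    """A typed joint with placement frames and range-of-motion limits.

    ``rom_limits`` maps DOF name -> (min, max) in degrees for rotations and
    millimetres for translations; missing rotational entries default to
    (-180, 180), missing translational entries to effectively unbounded.
    ``geometry`` optionally records the fitted geometric primitives the
    placement frame was built from (ball center or hinge condyle centers,
    plus the sagittal plane and previous-frame origin expressed in the parent
    frame); it is what the Monte Carlo joint-parameter perturbation acts on.
    """

    name: str
    joint_type: str
    frame_in_parent: FrameDef = field(default_factory=FrameDef)
    frame_in_child: FrameDef = field(default_factory=FrameDef)
    rom_limits: dict = field(default_factory=dict)
    geometry: Optional[dict] = None

    def __post_init__(self):
        if self.joint_type not in JOINT_DOF_NAMES:
            raise InvalidInputError(f"unknown joint type {self.joint_type!r}")
        for dof, (lo, hi) in self.rom_limits.items():
            if dof not in JOINT_DOF_NAMES[self.joint_type]:
                raise InvalidInputError(f"joint {self.name!r} has no DOF {dof!r}")
            if not lo < hi:
                raise InvalidInputError(f"ROM of {self.name}:{dof} needs min < max, got {(lo, hi)}")

    @property
    def dof_names(self) -> list:
        return list(JOINT_DOF_NAMES[self.joint_type])

    @property
    def n_dof(self) -> int:
        return len(JOINT_DOF_NAMES[self.joint_type])

    def limits(self, dof: str) -> tuple:
        """Effective (min, max) for one DOF: degrees (rotation) or mm (translation)."""
        if dof in self.rom_limits:
            return tuple(self.rom_limits[dof])
        if dof.startswith("t"):
            return (-_FREE_TRANSLATION_LIMIT, _FREE_TRANSLATION_LIMIT)
        return (-180.0, 180.0)


@dataclass
class SegmentSpec:
    """A rigid segment: its parent, the connecting joint and attached markers."""

    name: str
    parent: str  # parent segment name, or "ground"
    joint: JointSpec
    markers: dict = field(default_factory=dict)  # marker name -> local (3,) mm

    def __post_init__(self):
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}


class KinematicModel:
    """Validated tree of segments with a deterministic coordinate layout.

    Coordinates are ordered by pre-order traversal of the tree (parents
    before children, siblings in declaration order), joint DOFs in the
    abduction / internal-rotation / flexion order.  Build instances with
    :func:`assemble_model`.
    """

    def __init__(self, segments: list):
        self.segments = segments
        self.seg_index = {s.name: i for i, s in enumerate(segments)}
        self._parent_idx = np.array(
            [-1 if s.parent == GROUND else self.seg_index[s.parent] for s in segments]
        )
        self.coordinate_layout = [
            (s.joint.name, dof) for s in segments for dof in s.joint.dof_names
        ]
        self.coordinate_names = [f"{j}:{d}" for j, d in self.coordinate_layout]
        self.marker_names: list = []
        marker_seg, marker_local = [], []
        for i, s in enumerate(segments):
            for mname, mlocal in s.markers.items():
                self.marker_names.append(mname)
                marker_seg.append(i)
                marker_local.append(mlocal)
        self._marker_seg = np.array(marker_seg, dtype=int)
        self._marker_local = (
            np.asarray(marker_local, dtype=float) if marker_local else np.zeros((0, 3))
        )
        self.marker_segment = {m: segments[i].name for m, i in zip(self.marker_names, marker_seg)}
        self._compile()

    # -- structure ---------------------------------------------------------
    @property
    def n_dof(self) -> int:
        return len(self.coordinate_layout)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def joint(self, name: str) -> JointSpec:
        for s in self.segments:
            if s.joint.name == name:
                return s.joint
        raise KeyError(name)

    def segment_of_joint(self, name: str) -> SegmentSpec:
        for s in self.segments:
            if s.joint.name == name:
                return s
        raise KeyError(name)

    def neutral_pose(self) -> np.ndarray:
        return np.zeros(self.n_dof)

    def copy(self):
        import copy

        return assemble_model(copy.deepcopy(self.segments))

    # -- compiled arrays ---------------------------------------------------
    def _compile(self):
        n = len(self.segments)
        self._R_jp = np.empty((n, 3, 3))
        self._o_jp = np.empty((n, 3))
        self._R_jci = np.empty((n, 3, 3))
        self._o_jci = np.empty((n, 3))
        self._jtype = []
        self._dof_slice = []
        k = 0
        for i, s in enumerate(self.segments):
            self._R_jp[i] = s.joint.frame_in_parent.rotation
            self._o_jp[i] = s.joint.frame_in_parent.origin
            Rc = s.joint.frame_in_child.rotation
            self._R_jci[i] = Rc.T
            self._o_jci[i] = -Rc.T @ s.joint.frame_in_child.origin
            self._jtype.append(s.joint.joint_type)
            nd = s.joint.n_dof
            self._dof_slice.append(slice(k, k + nd))
            k += nd
        # per-DOF metadata
        self.dof_is_rotation = np.array(
            [not d.startswith("t") for _, d in self.coordinate_layout]
        )
        lo, hi = [], []
        for s in self.segments:
            for d in s.joint.dof_names:
                a, b = s.joint.limits(d)
                if d.startswith("t"):
                    lo.append(a)
                    hi.append(b)
                else:
                    lo.append(np.deg2rad(a))
                    hi.append(np.deg2rad(b))
        self.lower_bounds = np.array(lo) if lo else np.zeros(0)
        self.upper_bounds = np.array(hi) if hi else np.zeros(0)
        # ancestor DOF indices per segment (for the marker Jacobian)
        self._ancestor_dofs = []
        for i in range(n):
            idx = []
            j = i
            while j >= 0:
                sl = self._dof_slice[j]
                idx.extend(range(sl.start, sl.stop))
                j = self._parent_idx[j]
            self._ancestor_dofs.append(np.array(sorted(idx), dtype=int))
        # inverse map: markers affected by each DOF, plus their Jacobian rows
        affected = [[] for _ in range(self.n_dof)]
        for m, seg in enumerate(self._marker_seg):
            for d in self._ancestor_dofs[seg]:
                affected[d].append(m)
        self._dof_markers = [np.array(a, dtype=int) for a in affected]
        self._dof_rows = [
            (3 * a[:, None] + np.arange(3)).ravel() if len(a) else np.zeros(0, dtype=int)
            for a in self._dof_markers
        ]
        # flat layout for the JIT kernel
        self._jtype_code = np.array(
            [{"free6": 0, "ball3": 1, "hinge1": 2, "locked0": 3}[t] for t in self._jtype],
            dtype=np.int64)
        self._dof_start = np.array([sl.start for sl in self._dof_slice], dtype=np.int64)
        self._dm_off = np.zeros(self.n_dof + 1, dtype=np.int64)
        for d in range(self.n_dof):
            self._dm_off[d + 1] = self._dm_off[d] + len(self._dof_markers[d])
        self._dm_idx = (np.concatenate(self._dof_markers) if self.n_dof else
                        np.zeros(0)).astype(np.int64)
        self._marker_seg64 = self._marker_seg.astype(np.int64)

    # -- kinematics core ---------------------------------------------------
    def _fk(self, q: np.ndarray, want_jac: bool = False):
        """Segment world poses; optionally per-DOF world axes for the Jacobian.

        Returns (R (n,3,3), p (n,3)) and, when ``want_jac``, arrays
        ``axis (ndof,3)``, ``point (ndof,3)`` with the instantaneous world
        axis (and a point on it, for rotations) of every elemental DOF.
        """
        q = np.asarray(q, dtype=float)
        if q.shape != (self.n_dof,):
            raise InvalidInputError(f"pose vector must have length {self.n_dof}, got {q.shape}")
        n = len(self.segments)
        R = np.empty((n, 3, 3))
        p = np.empty((n, 3))
        axis = np.empty((self.n_dof, 3)) if want_jac else None
        point = np.empty((self.n_dof, 3)) if want_jac else None
        for i in range(n):
            par = self._parent_idx[i]
            if par < 0:
                Rp, pp = np.eye(3), np.zeros(3)
            else:
                Rp, pp = R[par], p[par]
            W = Rp @ self._R_jp[i]
            ow = pp + Rp @ self._o_jp[i]
            jt = self._jtype[i]
            sl = self._dof_slice[i]
            qj = q[sl]
            if jt == "free6":
                ow = ow + W @ qj[:3]
                Rx, Ry, Rz = _rot_x(qj[3]), _rot_y(qj[4]), _rot_z(qj[5])
                Rq = Rx @ Ry @ Rz
                if want_jac:
                    axis[sl.start:sl.start + 3] = W.T  # rows = world axes (W columns)
                    point[sl.start:sl.start + 3] = 0.0
                    WRx = W @ Rx
                    axis[sl.start + 3] = W[:, 0]
                    axis[sl.start + 4] = WRx[:, 1]
                    axis[sl.start + 5] = (WRx @ Ry)[:, 2]
                    point[sl.start + 3:sl.stop] = ow
            elif jt == "ball3":
                Rx, Ry = _rot_x(qj[0]), _rot_y(qj[1])
                Rq = Rx @ Ry @ _rot_z(qj[2])
                if want_jac:
                    WRx = W @ Rx
                    axis[sl.start] = W[:, 0]
                    axis[sl.start + 1] = WRx[:, 1]
                    axis[sl.start + 2] = (WRx @ Ry)[:, 2]
                    point[sl] = ow
            elif jt == "hinge1":
                Rq = _rot_z(qj[0])
                if want_jac:
                    axis[sl.start] = W[:, 2]
                    point[sl.start] = ow
            else:  # locked0
                Rq = np.eye(3)
            Rj = W @ Rq
            R[i] = Rj @ self._R_jci[i]
            p[i] = ow + Rj @ self._o_jci[i]
        return (R, p, axis, point) if want_jac else (R, p)

    def marker_positions_array(self, q: np.ndarray) -> np.ndarray:
        """(n_markers, 3) world marker positions at pose ``q``."""
        R, p = self._fk(q)
        if not self.marker_names:
            return np.zeros((0, 3))
        Rs = R[self._marker_seg]
        return p[self._marker_seg] + np.einsum("nij,nj->ni", Rs, self._marker_local)

    def marker_jacobian(self, q: np.ndarray):
        """Marker positions and their Jacobian d(marker xyz)/dq.

        Rotational DOF columns are ``a x (m - o)`` with ``a`` the world axis
        and ``o`` a point on it; translational columns are the world axis.
        Uses the JIT kernel when numba is importable, else the numpy path
        (:meth:`marker_jacobian_py`); both agree to machine precision.
        """
        if _fastkin.HAVE_NUMBA:
            q = np.ascontiguousarray(q, dtype=float)
            if q.shape != (self.n_dof,):
                raise InvalidInputError(f"pose vector must have length {self.n_dof}")
            _, _, mk, J = _fastkin.fk_marker_jac(
                self._parent_idx, self._jtype_code, self._dof_start,
                self._R_jp, self._o_jp, self._R_jci, self._o_jci, q,
                self._marker_seg64, self._marker_local, self._dm_idx, self._dm_off,
                self.dof_is_rotation, True)
            return mk, J
        return self.marker_jacobian_py(q)

    def marker_jacobian_py(self, q: np.ndarray):
        """Reference numpy implementation of :meth:`marker_jacobian`."""
        R, p, axis, point = self._fk(q, want_jac=True)
        Rs = R[self._marker_seg]
        mk = p[self._marker_seg] + np.einsum("nij,nj->ni", Rs, self._marker_local)
        J = np.zeros((len(mk) * 3, self.n_dof))
        is_rot = self.dof_is_rotation
        for d in range(self.n_dof):
            idx = self._dof_markers[d]
            if not len(idx):
                continue
            if is_rot[d]:
                contrib = np.cross(axis[d], mk[idx] - point[d])
            else:
                contrib = np.broadcast_to(axis[d], (len(idx), 3))
            J[self._dof_rows[d], d] = contrib.ravel()
        return mk, J


@dataclass(frozen=True)
class FKResult:
    """World poses of every segment plus world marker positions."""

    segment_names: list
    rotations: np.ndarray  # (n_segments, 3, 3), local -> global
    origins: np.ndarray  # (n_segments, 3) mm
    marker_positions: dict  # marker name -> (3,) mm

    def segment_pose(self, name: str) -> FrameDef:
        i = self.segment_names.index(name)
        return FrameDef(origin=self.origins[i], rotation=self.rotations[i])


@dataclass(frozen=True)
class RomViolation:
    joint: str
    dof: str
    value_deg: float
    limit_deg: tuple
    exceedance_deg: float  # signed: >0 above max, <0 below min


def assemble_model(segments: list) -> KinematicModel:
    """Validate segment specs and build a :class:`KinematicModel`.

    Exactly one segment must attach to ground; parents must exist and precede
    use; the graph must be a tree (every segment reachable from the root).
    """
    names = [s.name for s in segments]
    if len(set(names)) != len(names):
        raise InvalidInputError("duplicate segment names")
    jnames = [s.joint.name for s in segments]
    if len(set(jnames)) != len(jnames):
        raise InvalidInputError("duplicate joint names")
    mnames = [m for s in segments for m in s.markers]
    if len(set(mnames)) != len(mnames):
        raise InvalidInputError("duplicate marker names across segments")
    roots = [s.name for s in segments if s.parent == GROUND]
    if len(roots) != 1:
        raise InvalidTopologyError(f"expected exactly one root segment on ground, got {roots}")
    known = set(names) | {GROUND}
    for s in segments:
        if s.parent not in known:
            raise InvalidTopologyError(f"segment {s.name!r} references unknown parent {s.parent!r}")
    # pre-order traversal; detects cycles/orphans (unreachable segments)
    children: dict = {n: [] for n in names}
    for s in segments:
        if s.parent != GROUND:
            children[s.parent].append(s.name)
    by_name = {s.name: s for s in segments}
    ordered, stack = [], [roots[0]]
    while stack:
        cur = stack.pop(0)
        ordered.append(by_name[cur])
        stack = children[cur] + stack
    if len(ordered) != len(segments):
        missing = set(names) - {s.name for s in ordered}
        raise InvalidTopologyError(f"segments not reachable from the root (cycle?): {sorted(missing)}")
    return KinematicModel(ordered)


def forward_kinematics(model: KinematicModel, q) -> FKResult:
    """Map a pose vector to world segment poses and marker positions."""
    R, p = model._fk(np.asarray(q, dtype=float))
    mk = model.marker_positions_array(q)
    return FKResult(
        segment_names=[s.name for s in model.segments],
        rotations=R,
        origins=p,
        marker_positions={n: mk[i] for i, n in enumerate(model.marker_names)},
    )


def check_rom(model: KinematicModel, q) -> list:
    """Range-of-motion violations of rotational DOFs (closed-interval limits)."""
    q = np.asarray(q, dtype=float)
    if q.shape != (model.n_dof,):
        raise InvalidInputError(f"pose vector must have length {model.n_dof}")
    out = []
    for k, (jname, dof) in enumerate(model.coordinate_layout):
        if not model.dof_is_rotation[k]:
            continue
        lo, hi = np.rad2deg(model.lower_bounds[k]), np.rad2deg(model.upper_bounds[k])
        v = np.rad2deg(q[k])
        if v > hi:
            out.append(RomViolation(jname, dof, v, (lo, hi), v - hi))
        elif v < lo:
            out.append(RomViolation(jname, dof, v, (lo, hi), v - lo))
    return out


def parse_marker_name(name: str) -> dict:
    """Split a marker name into leg prefix, side and anatomy token.

    The naming grammar prefixes leg markers with f/m/r (front/middle/rear)
    plus l/r (left/right), followed by the anatomy token (th, pet, abd, cox,
    tro, fe, ti, mt, ta) and an optional disambiguating suffix, e.g.
    ``ml_fe_b`` = middle-left femur, second marker.  Trunk markers carry no
    leg prefix (``th_a``, ``head_a``...).
    """
    parts = name.split("_")
    if parts[0] in _LEG_PREFIXES:
        return {
            "leg": parts[0],
            "row": {"f": "front", "m": "middle", "r": "rear"}[parts[0][0]],
            "side": {"l": "left", "r": "right"}[parts[0][1]],
            "token": parts[1],
            "suffix": "_".join(parts[2:]) or None,
        }
    return {"leg": None, "row": None, "side": None, "token": parts[0],
            "suffix": "_".join(parts[1:]) or None}
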