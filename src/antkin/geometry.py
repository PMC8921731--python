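"""Joint geometry from articular surfaces.

Centers of rotation of ball-and-socket joints are taken as centers of spheres
fitted to the articular surface of the exoskeleton; hinge axes are lines
through the centers of two spheres fitted to the condyles.  Segment coordinate
systems are built from these primitives plus the sagittal plane (defined by
the two propodeal spiracles): all frames are right-handed and orthonormal,
hinge z-axes point medially, y-axes point toward the previous segment of the
chain.

Units are millimetres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateGeometryError, InvalidInputError

__all__ = [
    "SphereFit",
    "HingeAxisFit",
    "PlaneDef",
    "FrameDef",
    "fit_sphere",
    "fit_hinge_axis",
    "define_sagittal_plane",
    "build_thorax_frame",
    "build_hinge_frame",
    "hinge_frame_from_centers",
    "build_ball_frame",
]

# Relative singular-value cutoff below which a point cloud is declared coplanar.
_COND_RTOL = 1e-9
# Two fitted centers closer than this (mm) cannot define an axis.
_COINCIDENT_TOL = 1e-9


def _as_points(points, min_points: int) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidInputError(f"expected an (n, 3) array of points, got shape {pts.shape}")
    if len(pts) < min_points:
        raise InvalidInputError(f"need at least {min_points} points, got {len(pts)}")
    if not np.all(np.isfinite(pts)):
        raise InvalidInputError("point cloud contains non-finite coordinates")
    return pts


def _unit(v: np.ndarray, err: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(err)
    return v / n


@dataclass(frozen=True)
class SphereFit:
    """Least-squares sphere through an articular-surface point cloud."""

    center: np.ndarray
    radius: float
    rms_residual: float
    n_points: int

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise InvalidInputError("sphere radius must be positive")
        if self.rms_residual < 0:
            raise InvalidInputError("rms_residual must be non-negative")
        if self.n_points < 4:
            raise InvalidInputError("a sphere fit needs at least 4 points")


@dataclass(frozen=True)
class HingeAxisFit:
    """Hinge rotation axis: the line through two fitted condyle-sphere centers."""

    condyle_a: SphereFit
    condyle_b: SphereFit
    axis_dir: np.ndarray
    midpoint: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "axis_dir", np.asarray(self.axis_dir, dtype=float))
        object.__setattr__(self, "midpoint", np.asarray(self.midpoint, dtype=float))
        if abs(np.linalg.norm(self.axis_dir) - 1.0) > 1e-12:
            raise InvalidInputError("axis_dir must be a unit vector")


@dataclass(frozen=True)
class PlaneDef:
    """A plane given by a unit normal and one point on it (e.g. the sagittal plane)."""

    unit_normal: np.ndarray
    point_on_plane: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "unit_normal", np.asarray(self.unit_normal, dtype=float))
        object.__setattr__(self, "point_on_plane", np.asarray(self.point_on_plane, dtype=float))
        if abs(np.linalg.norm(self.unit_normal) - 1.0) > 1e-12:
            raise InvalidInputError("unit_normal must be a unit vector")


@dataclass(frozen=True)
class FrameDef:
    """A segment/joint coordinate system: origin plus a local->reference rotation.

    ``rotation`` columns are the frame's x, y, z axes expressed in the
    reference frame; the matrix is orthonormal with determinant +1.
    """

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        R = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", R)
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-10:
            raise InvalidInputError("rotation must be orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-10:
            raise InvalidInputError("rotation must be right-handed (det +1)")

    @property
    def x(self) -> np.ndarray:
        return self.rotation[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.rotation[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.rotation[:, 2]


def read_point_cloud(path) -> np.ndarray:
    """Read an (n, 3) point cloud in mm.

    Whitespace- or comma-separated XYZ text is parsed directly; ``.ply`` and
    ``.stl`` files are read vertices-only through trimesh (no topology used).
    """
    p = str(path)
    if p.lower().endswith((".ply", ".stl")):
        import trimesh

        mesh = trimesh.load(p, process=False)
        return np.asarray(mesh.vertices, dtype=float)
    with open(p) as fh:
        text = fh.read().replace(",", " ")
    rows = [ln.split() for ln in text.splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")]
    try:
        pts = np.array([[float(v) for v in r[:3]] for r in rows])
    except (ValueError, IndexError) as exc:
        raise InvalidInputError(f"{path}: not an XYZ table ({exc})") from exc
    return pts


def fit_sphere(points, refine: bool = True) -> SphereFit:
    """Fit a sphere to a point cloud by linear least squares.

    The algebraic (Coope) formulation solves ``[2p | 1] [c; k] = |p|^2`` for
    the center ``c`` and ``k = r^2 - |c|^2``, which is exact on noiseless data.
    With ``refine=True`` a Gauss-Newton pass on the geometric distances
    ``|p - c| - r`` polishes the estimate (matters only for noisy, partial
    caps).

    Raises
    ------
    InvalidInputError
        Fewer than 4 points.
    DegenerateGeometryError
        (Nearly) coplanar cloud: the linear system is rank-deficient.
    """
    pts = _as_points(points, 4)
    A = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = np.sum(pts**2, axis=1)
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] < _COND_RTOL * sv[0]:
        raise DegenerateGeometryError("point cloud is (nearly) coplanar; sphere fit is ill-posed")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("algebraic sphere fit produced a non-positive radius")
    radius = float(np.sqrt(r2))

    if refine:
        def resid(x):
            return np.linalg.norm(pts - x[:3], axis=1) - x[3]

        out = least_squares(resid, np.append(center, radius), method="lm", xtol=1e-15, ftol=1e-15)
        if out.x[3] > 0:
            center, radius = out.x[:3], float(out.x[3])

    rms = float(np.sqrt(np.mean((np.linalg.norm(pts - center, axis=1) - radius) ** 2)))
    return SphereFit(center=center, radius=radius, rms_residual=rms, n_points=len(pts))


def fit_hinge_axis(condyle_points_a, condyle_points_b, refine: bool = True) -> HingeAxisFit:
    """Hinge axis through the centers of two condyle sphere fits."""
    fa = fit_sphere(condyle_points_a, refine=refine)
    fb = fit_sphere(condyle_points_b, refine=refine)
    delta = fb.center - fa.center
    if np.linalg.norm(delta) < _COINCIDENT_TOL:
        raise DegenerateGeometryError("condyle centers coincide; hinge axis undefined")
    axis = delta / np.linalg.norm(delta)
    mid = 0.5 * (fa.center + fb.center)
    return HingeAxisFit(condyle_a=fa, condyle_b=fb, axis_dir=axis, midpoint=mid)


def define_sagittal_plane(spiracle_points_left, spiracle_points_right) -> PlaneDef:
    """Sagittal plane from the two propodeal spiracles.

    The plane is perpendicular to the line joining the two fitted spiracle
    centers and contains their midpoint P_SP.  The normal points from the
    first (left) toward the second (right) center.
    """
    fl = fit_sphere(spiracle_points_left)
    fr = fit_sphere(spiracle_points_right)
    delta = fr.center - fl.center
    if np.linalg.norm(delta) < _COINCIDENT_TOL:
        raise DegenerateGeometryError("spiracle centers coincide; sagittal plane undefined")
    return PlaneDef(unit_normal=delta / np.linalg.norm(delta),
                    point_on_plane=0.5 * (fl.center + fr.center))


def _lateral_axes(y: np.ndarray, sagittal: PlaneDef, flip_x: bool):
    """x, z completing a right-handed triad from an anterior/proximal y.

    x = y x n_s (so z = x x y = +n_s for y ⟂ n_s); ``flip_x`` selects the
    mirrored convention.
    """
    x = np.cross(y, sagittal.unit_normal)
    x = _unit(x, "y direction is parallel to the sagittal normal")
    if flip_x:
        x = -x
    z = np.cross(x, y)
    return x, z


def build_thorax_frame(P_h, P_a, sagittal: PlaneDef, flip_x: bool = False) -> FrameDef:
    """Thorax coordinate system.

    Origin at the midpoint of the segment joining the thorax/head and
    thorax/abdomen sphere centers (P_h, P_a); y along that segment pointing
    anteriorly (toward P_h); x perpendicular to both y and the sagittal
    normal; z completes the right-handed triad.
    """
    P_h = np.asarray(P_h, dtype=float)
    P_a = np.asarray(P_a, dtype=float)
    seg = P_h - P_a
    y = _unit(seg, "P_h and P_a coincide")
    if np.linalg.norm(np.cross(y, sagittal.unit_normal)) < 1e-6:
        raise DegenerateGeometryError("P_h - P_a is parallel to the sagittal normal")
    x, z = _lateral_axes(y, sagittal, flip_x)
    return FrameDef(origin=0.5 * (P_h + P_a), rotation=np.column_stack([x, y, z]))


def build_hinge_frame(axis: HingeAxisFit, previous_frame_origin, sagittal: PlaneDef) -> FrameDef:
    """Joint frame of a hinge.

    Origin at the axis midpoint; z along the rotation axis pointing medially
    (sign whose dot product with the vector from the origin to its orthogonal
    projection on the sagittal plane is positive; for a joint lying on the
    plane itself the sign of the dot product with the plane normal is used);
    y perpendicular to z, pointing toward the previous segment's origin;
    x = y x z.
    """
    return _hinge_frame(axis.axis_dir, axis.midpoint, previous_frame_origin, sagittal)


def hinge_frame_from_centers(center_a, center_b, previous_frame_origin,
                             sagittal: PlaneDef) -> FrameDef:
    """:func:`build_hinge_frame` from two condyle centers directly.

    Used when the axis-defining points are already known (or have been
    perturbed) without refitting condyle spheres.
    """
    ca = np.asarray(center_a, dtype=float)
    cb = np.asarray(center_b, dtype=float)
    axis_dir = _unit(cb - ca, "condyle centers coincide; hinge axis undefined")
    return _hinge_frame(axis_dir, 0.5 * (ca + cb), previous_frame_origin, sagittal)


def _hinge_frame(axis_dir, midpoint, previous_frame_origin, sagittal: PlaneDef) -> FrameDef:
    prev = np.asarray(previous_frame_origin, dtype=float)
    origin = np.asarray(midpoint, dtype=float)
    n = sagittal.unit_normal
    to_plane = (sagittal.point_on_plane - origin) @ n * n  # origin -> its foot on the plane
    z = np.asarray(axis_dir, dtype=float).copy()
    if np.linalg.norm(to_plane) > 1e-9:
        if z @ to_plane < 0:
            z = -z
    elif z @ n < 0:  # midline joint: "medial" is ambiguous, orient along the normal
        z = -z
    v = prev - origin
    y = v - (v @ z) * z
    y = _unit(y, "previous frame origin lies on the hinge axis")
    x = np.cross(y, z)
    return FrameDef(origin=origin, rotation=np.column_stack([x, y, z]))


def build_ball_frame(center, previous_frame_origin, sagittal: PlaneDef,
                     flip_x: bool = False) -> FrameDef:
    """Joint frame of a ball-and-socket joint.

    Origin at the fitted sphere center; y toward the previous segment's
    origin (pointing proximally); x perpendicular to y and the sagittal
    normal; z completes the right-handed triad.
    """
    center = np.asarray(center, dtype=float)
    prev = np.asarray(previous_frame_origin, dtype=float)
    y = _unit(prev - center, "ball center coincides with the previous frame origin")
    if np.linalg.norm(np.cross(y, sagittal.unit_normal)) < 1e-6:
        raise DegenerateGeometryError("proximal direction is parallel to the sagittal normal")
    x, z = _lateral_axes(y, sagittal, flip_x)
    return FrameDef(origin=center, rotation=np.column_stack([x, y, z]))
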