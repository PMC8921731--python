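"""Model scaling and marker-based inverse kinematics.

Scaling matches the model (built from one specimen's µ-CT geometry) to the
filmed specimen via per-segment ratios of inter-marker distances.  Inverse
kinematics then solves, frame by frame, the bounded weighted least-squares
problem

    min_q  Σ_i w_i ‖x_i^obs − x_i^model(q)‖²   s.t.  ROM bounds on q,

reporting per-frame weighted marker RMSE.  Frame 0 is solved with a
multi-start from the neutral pose; later frames are warm-started from the
previous solution.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DegenerateGeometryError, InvalidInputError
from .geometry import FrameDef
from .model import GROUND, KinematicModel, assemble_model
from .trial import MarkerTrial

__all__ = [
    "ScaleSet",
    "IKSettings",
    "IKResult",
    "compute_scale_factors",
    "apply_scaling",
    "solve_ik_frame",
    "solve_ik_trial",
    "range_of_motion",
]

# Gauss-Newton Hessian eigenvalue ratio below which a frame is flagged
# as weakly observable (e.g. axial rotation about a 2-marker line).
_OBSERVABILITY_RTOL = 1e-8


@dataclass(frozen=True)
class ScaleSet:
    """Positive per-segment scale factors."""

    factors: dict

    def __post_init__(self):
        for k, v in self.factors.items():
            if v <= 0:
                raise InvalidInputError(f"scale factor of {k!r} must be positive, got {v}")

    def __getitem__(self, segment: str) -> float:
        return self.factors[segment]


@dataclass
class IKSettings:
    """Solver settings for the per-frame least-squares IK."""

    marker_weights: dict = field(default_factory=dict)  # name -> weight, default 1
    enforce_rom: bool = True
    cost_tolerance: float = 1e-10  # relative cost-reduction tolerance (mm^2 scale)
    step_tolerance: float = 1e-12  # relative step-norm tolerance
    max_iterations: int = 200
    warm_start: bool = True
    multi_starts: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.cost_tolerance <= 0:
            raise InvalidInputError("cost tolerance must be positive")
        if any(w < 0 for w in self.marker_weights.values()):
            raise InvalidInputError("marker weights must be non-negative")

    def weight(self, marker: str) -> float:
        return float(self.marker_weights.get(marker, 1.0))


@dataclass
class IKResult:
    """Joint-coordinate trajectories plus per-frame fit quality.

    ``trajectory`` is (n_frames, n_dof) with rotations in degrees and
    translations in mm, in the model's coordinate layout order.
    """

    coordinate_names: list
    dof_is_rotation: np.ndarray
    trajectory: np.ndarray
    per_frame_rmse: np.ndarray  # mm
    converged: np.ndarray  # bool per frame
    solved: np.ndarray  # bool per frame (False = insufficient markers, excluded)
    warnings: list
    rate: float
    body_length_mm: Optional[float] = None

    def __post_init__(self):
        if np.any(self.per_frame_rmse[self.solved] < 0):
            raise InvalidInputError("RMSE must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.trajectory.shape[0]

    @property
    def average_rmse(self) -> float:
        """Arithmetic mean over solved frames of the weighted marker RMSE (mm)."""
        if not self.solved.any():
            return float("nan")
        return float(np.mean(self.per_frame_rmse[self.solved]))

    @property
    def normalized_rmse(self) -> Optional[float]:
        """Average RMSE as a fraction of body length, if a length was supplied."""
        if self.body_length_mm is None:
            return None
        return self.average_rmse / self.body_length_mm

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.trajectory, columns=self.coordinate_names)
        df.insert(0, "time", np.arange(self.n_frames) / self.rate)
        df["marker_rmse_mm"] = self.per_frame_rmse
        return df


def _segment_marker_pairs(model: KinematicModel, trial: MarkerTrial) -> dict:
    pairs: dict = {}
    have = set(trial.marker_names)
    for seg in model.segments:
        names = [m for m in seg.markers if m in have]
        if len(names) >= 2:
            pairs[seg.name] = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    return pairs


def compute_scale_factors(model: KinematicModel, trial: MarkerTrial,
                          marker_pairs_per_segment: Optional[dict] = None) -> ScaleSet:
    """Per-segment scale = mean experimental / model inter-marker distance.

    Segments without a measurable marker pair inherit the parent's factor
    (the root defaults to 1).  With ``marker_pairs_per_segment`` omitted,
    every within-segment pair present in the trial is used.
    """
    pairs = marker_pairs_per_segment or _segment_marker_pairs(model, trial)
    if not pairs:
        raise InvalidInputError("no within-segment marker pairs available for scaling")
    raw: dict = {}
    for seg_name, seg_pairs in pairs.items():
        seg = model.segments[model.seg_index[seg_name]]
        ratios = []
        for a, b in seg_pairs:
            ref = np.linalg.norm(seg.markers[a] - seg.markers[b])
            if ref < 1e-12:
                raise DegenerateGeometryError(
                    f"model markers {a!r}/{b!r} coincide; cannot scale {seg_name!r}")
            d = np.linalg.norm(trial.marker(a) - trial.marker(b), axis=1)
            d = d[np.isfinite(d)]
            if len(d):
                ratios.append(float(np.mean(d)) / ref)
        if ratios:
            raw[seg_name] = float(np.mean(ratios))
    if not raw:
        raise InvalidInputError("no marker pair had valid samples in the trial")
    factors: dict = {}
    for seg in model.segments:  # pre-order: parents first
        if seg.name in raw:
            factors[seg.name] = raw[seg.name]
        elif seg.parent == GROUND:
            factors[seg.name] = 1.0
        else:
            factors[seg.name] = factors[seg.parent]
    return ScaleSet(factors=factors)


def apply_scaling(model: KinematicModel, scales: ScaleSet) -> KinematicModel:
    """Scale joint placements and marker positions; rotations and ROM unchanged.

    A joint's placement translation lives in the parent segment's frame and
    is scaled by the parent's factor (the root placement is untouched);
    marker local positions scale with their owning segment.  Geometry
    provenance points (in parent coordinates) scale with the parent so that
    Monte Carlo perturbations act on the scaled geometry.
    """
    segments = copy.deepcopy(model.segments)
    for seg in segments:
        f_parent = 1.0 if seg.parent == GROUND else scales[seg.parent]
        f_own = scales[seg.name]
        fp = seg.joint.frame_in_parent
        seg.joint.frame_in_parent = FrameDef(origin=fp.origin * f_parent, rotation=fp.rotation)
        fc = seg.joint.frame_in_child
        seg.joint.frame_in_child = FrameDef(origin=fc.origin * f_own, rotation=fc.rotation)
        seg.markers = {k: v * f_own for k, v in seg.markers.items()}
        if seg.joint.geometry is not None:
            g = dict(seg.joint.geometry)
            for key in ("center", "condyle_a", "condyle_b", "prev_origin", "sagittal_point"):
                if key in g:
                    g[key] = np.asarray(g[key], dtype=float) * f_parent
            seg.joint.geometry = g
    return assemble_model(segments)


class _FrameProblem:
    """Weighted residuals and Jacobian for one frame, with a one-entry cache
    (least_squares evaluates fun and jac at the same point)."""

    def __init__(self, model, marker_idx, targets, sqw):
        self.model = model
        self.idx = marker_idx
        self.all_markers = len(marker_idx) == len(model.marker_names) and \
            np.array_equal(marker_idx, np.arange(len(marker_idx)))
        self.rows = (3 * marker_idx[:, None] + np.arange(3)).ravel()
        self.targets = targets
        self.sqw = sqw  # sqrt(weight) per observed marker
        self._key = None
        self._mk = None
        self._J = None

    def _eval(self, q):
        key = q.tobytes()
        if key != self._key:
            mk, J = self.model.marker_jacobian(q)
            if self.all_markers:
                self._mk, self._J = mk, J
            else:
                self._mk = mk[self.idx]
                self._J = J[self.rows]
            self._key = key
        return self._mk, self._J

    def fun(self, q):
        mk, _ = self._eval(q)
        return ((mk - self.targets) * self.sqw[:, None]).ravel()

    def jac(self, q):
        _, J = self._eval(q)
        return J * np.repeat(self.sqw, 3)[:, None]


def _bounds(model: KinematicModel, settings: IKSettings):
    if settings.enforce_rom:
        return model.lower_bounds, model.upper_bounds
    return -np.inf, np.inf


def solve_ik_frame(model: KinematicModel, observed_markers: dict, settings: IKSettings,
                   q_init) -> tuple:
    """Solve one frame of IK.

    Returns ``(q, rmse, status)`` where ``status`` is a dict with keys
    ``converged``, ``cost``, ``nfev`` and ``warning`` (None or
    ``"low_observability"`` when the Gauss-Newton Hessian is near-singular).
    Markers absent from the model or with non-finite coordinates are ignored.
    """
    names, targets, sqw = [], [], []
    midx = {m: i for i, m in enumerate(model.marker_names)}
    for name, pos in observed_markers.items():
        pos = np.asarray(pos, dtype=float)
        if name in midx and np.all(np.isfinite(pos)) and settings.weight(name) > 0:
            names.append(name)
            targets.append(pos)
            sqw.append(np.sqrt(settings.weight(name)))
    if 3 * len(names) < model.n_dof:
        raise InvalidInputError(
            f"{len(names)} usable markers provide {3 * len(names)} coordinates; "
            f"cannot determine a {model.n_dof}-DOF pose")
    idx = np.array([midx[n] for n in names], dtype=int)
    prob = _FrameProblem(model, idx, np.asarray(targets), np.asarray(sqw))
    lo, hi = _bounds(model, settings)
    q0 = np.clip(np.asarray(q_init, dtype=float), lo, hi)
    res = least_squares(
        prob.fun, q0, jac=prob.jac, bounds=(lo, hi), method="trf",
        ftol=settings.cost_tolerance, xtol=settings.step_tolerance, gtol=None,
        max_nfev=settings.max_iterations, x_scale="jac",
    )
    J = prob.jac(res.x)
    ev = np.linalg.eigvalsh(J.T @ J)
    warning = "low_observability" if ev[-1] <= 0 or ev[0] < _OBSERVABILITY_RTOL * ev[-1] else None
    w2 = np.asarray(sqw) ** 2
    d2 = np.sum((prob._eval(res.x)[0] - prob.targets) ** 2, axis=1)
    rmse = float(np.sqrt(np.sum(w2 * d2) / np.sum(w2)))
    status = {"converged": bool(res.status > 0), "cost": float(res.cost),
              "nfev": int(res.nfev), "warning": warning}
    return res.x, rmse, status


def _centroid_init(model: KinematicModel, observed: dict, q: np.ndarray) -> np.ndarray:
    """Shift free-base translations so model and observed centroids align."""
    root = model.segments[0]
    if root.joint.joint_type != "free6":
        return q
    obs = np.array([p for p in observed.values() if np.all(np.isfinite(p))])
    if not len(obs):
        return q
    mk = model.marker_positions_array(q)
    W = root.joint.frame_in_parent.rotation  # base joint frame in ground
    q = q.copy()
    q[:3] += W.T @ (obs.mean(axis=0) - mk.mean(axis=0))
    return q


def solve_ik_trial(model: KinematicModel, trial: MarkerTrial, settings: IKSettings,
                   q_init_trajectory: Optional[np.ndarray] = None,
                   body_length_mm: Optional[float] = None) -> IKResult:
    """Solve IK over a whole (preprocessed) trial.

    Frame 0 uses ``settings.multi_starts`` seeded starts around the neutral
    pose (with the floating base pre-aligned to the observed marker
    centroid); subsequent frames warm-start from the previous solution.
    Frames with too few usable markers are flagged unsolved and excluded from
    averages.  ``q_init_trajectory`` (n_frames, n_dof, radians/mm) overrides
    the warm-start chain, e.g. with a baseline solution during Monte Carlo.
    """
    n, nd = trial.n_frames, model.n_dof
    traj = np.zeros((n, nd))
    rmse = np.full(n, np.nan)
    converged = np.zeros(n, dtype=bool)
    solved = np.zeros(n, dtype=bool)
    warnings: list = []
    rng = np.random.default_rng(settings.seed)
    lo, hi = _bounds(model, settings)
    span = np.where(np.isfinite(hi - lo), hi - lo, 0.0)
    q_prev = None
    for f in range(n):
        observed = trial.frame_dict(f)
        try:
            if q_init_trajectory is not None:
                starts = [np.asarray(q_init_trajectory[f], dtype=float)]
            elif q_prev is not None and settings.warm_start:
                starts = [q_prev]
            else:
                base = _centroid_init(model, observed, model.neutral_pose())
                starts = [base]
                for _ in range(max(0, settings.multi_starts - 1)):
                    offs = rng.uniform(-0.25, 0.25, nd) * span
                    starts.append(np.clip(base + offs, lo, hi))
            best = None
            for q0 in starts:
                q, r, status = solve_ik_frame(model, observed, settings, q0)
                if best is None or status["cost"] < best[2]["cost"]:
                    best = (q, r, status)
            q, r, status = best
        except InvalidInputError as exc:
            warnings.append((f, str(exc)))
            continue
        traj[f] = q
        rmse[f] = r
        converged[f] = status["converged"]
        solved[f] = True
        if status["warning"]:
            warnings.append((f, status["warning"]))
        q_prev = q
    out = traj.copy()
    out[:, model.dof_is_rotation] = np.rad2deg(out[:, model.dof_is_rotation])
    return IKResult(
        coordinate_names=list(model.coordinate_names),
        dof_is_rotation=model.dof_is_rotation.copy(),
        trajectory=out,
        per_frame_rmse=rmse,
        converged=converged,
        solved=solved,
        warnings=warnings,
        rate=trial.rate,
        body_length_mm=body_length_mm,
    )


def range_of_motion(result: IKResult) -> pd.Series:
    """Observed span (max - min) of each coordinate over solved frames.

    Degrees for rotations, mm for translations; follows the convention of
    reporting a single span per DOF over the gait cycle.
    """
    if not result.solved.any():
        raise InvalidInputError("no solved frames")
    t = result.trajectory[result.solved]
    return pd.Series(t.max(axis=0) - t.min(axis=0), index=result.coordinate_names)
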