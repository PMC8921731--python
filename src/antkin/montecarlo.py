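"""Monte Carlo propagation of model parameter uncertainties through IK.

Two uncertainty sources are modelled, each with uniform draws inside its
zone.  Model-marker placements get independent offsets inside a sphere
(default radius 0.4 mm, a typical camera-calibration residual at this scale).
Joint geometrical parameters get spherical zones for ball-and-socket centers
and cylindrical zones for hinge axes (default radius 0.2 mm, the
operator-repeatability of articular-surface identification); the cylindrical
zone is realised by offsetting each of the two axis-defining condyle centers
inside a ball of the zone radius, which perturbs both the location and the
orientation of the axis while keeping it inside the stated cylinder.

Each iteration solves the full trial with a freshly perturbed model.  Across
iterations, per-DOF mean and SD trajectories are formed and the coverage
interval is defined as twice the standard deviation.  The sensitivity
statistic is the signal-to-noise ratio SNR = Ps / Pn per DOF, with Ps the
peak-to-peak amplitude of the mean joint-angle trajectory and Pn the maximum
coverage interval over the gait cycle.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, InvalidInputError, InvalidParameterError
from .geometry import FrameDef, PlaneDef, build_ball_frame
from .ik import IKSettings, solve_ik_trial
from .model import KinematicModel, assemble_model
from .trial import MarkerTrial

__all__ = [
    "PerturbationSpec",
    "MCResult",
    "SNRReport",
    "sample_uniform_ball",
    "perturb_marker_set",
    "perturb_joint_parameters",
    "run_monte_carlo",
    "compute_snr",
    "summarize_snr",
    "JOINT_KIND_ORDER",
]

#: Per-joint summary rows, proximal to distal.
JOINT_KIND_ORDER = [
    "thorax/head", "thorax/abdomen", "thorax/cox", "cox/tro",
    "tro/fe", "fe/ti", "ti/mt", "mt/ta",
]

_TOKEN_TO_KIND = {
    "head": "thorax/head", "abdomen": "thorax/abdomen", "petiole": "petiole",
    "cox": "thorax/cox", "tro": "cox/tro", "fe": "tro/fe",
    "ti": "fe/ti", "mt": "ti/mt", "ta": "mt/ta",
}
_LEGS = ("fl", "fr", "ml", "mr", "rl", "rr")


@dataclass(frozen=True)
class PerturbationSpec:
    """What to perturb, how much, and how many Monte Carlo iterations."""

    target: str  # "model_markers" | "joint_parameters"
    radius: float  # mm
    n_iterations: int = 1000
    master_seed: int = 0

    def __post_init__(self):
        if self.target not in ("model_markers", "joint_parameters"):
            raise InvalidInputError(f"unknown perturbation target {self.target!r}")
        if self.radius < 0:
            raise InvalidParameterError("perturbation radius must be >= 0")
        if self.n_iterations < 1:
            raise InvalidParameterError("need at least one iteration")


@dataclass
class MCResult:
    """Per-DOF mean/SD/coverage trajectories over Monte Carlo iterations.

    Trajectories are (n_dof, n_frames): rotations in degrees, base
    translations in mm.  ``coverage`` is ``coverage_multiplier * sd`` (the
    full width of the uncertainty band, by default twice the SD).
    """

    coordinate_names: list
    dof_is_rotation: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    coverage: np.ndarray
    n_success: int
    failures: list  # (iteration, reason)
    seed: int
    coverage_multiplier: float
    rate: float
    spec: Optional[PerturbationSpec] = None

    @property
    def n_iterations(self) -> int:
        return self.n_success + len(self.failures)

    def to_frames(self) -> dict:
        """mean/sd/coverage as tidy DataFrames (coordinates x frames)."""
        t = np.arange(self.mean.shape[1]) / self.rate
        return {
            key: pd.DataFrame(getattr(self, key), index=self.coordinate_names, columns=t)
            for key in ("mean", "sd", "coverage")
        }


@dataclass
class SNRReport:
    """Per-DOF signal power, noise power and their ratio.

    ``per_dof`` is indexed by coordinate name with columns joint, dof,
    joint_kind, leg, Ps, Pn, snr.  DOFs whose noise power is zero are listed
    in ``excluded`` with a note instead of reporting an infinite ratio.
    """

    per_dof: pd.DataFrame
    excluded: list = field(default_factory=list)


def sample_uniform_ball(radius: float, rng: np.random.Generator, size: Optional[int] = None):
    """Uniform draw(s) from the closed 3-ball of the given radius.

    Radius follows ``R * u^(1/3)`` (volume-uniform), direction is an
    isotropic unit vector; the mean norm is ``3R/4``.
    """
    if radius < 0:
        raise InvalidParameterError("radius must be >= 0")
    n = 1 if size is None else size
    d = rng.normal(size=(n, 3))
    norms = np.linalg.norm(d, axis=1)
    while np.any(norms < 1e-300):  # pathologically tiny normal draws
        bad = norms < 1e-300
        d[bad] = rng.normal(size=(int(bad.sum()), 3))
        norms = np.linalg.norm(d, axis=1)
    r = radius * rng.uniform(size=n) ** (1.0 / 3.0)
    out = d / norms[:, None] * r[:, None]
    return out[0] if size is None else out


def perturb_marker_set(model: KinematicModel, radius: float,
                       rng: np.random.Generator) -> KinematicModel:
    """Offset every model marker's local position inside a uniform ball.

    One independent draw per marker, fixed over the trial: this models
    marker placement/identification error, not per-frame tracking noise.
    """
    segments = copy.deepcopy(model.segments)
    for seg in segments:
        for name in seg.markers:
            seg.markers[name] = seg.markers[name] + sample_uniform_ball(radius, rng)
    return assemble_model(segments)


def _hinge_frame_aligned(pa: np.ndarray, pb: np.ndarray, prev: np.ndarray,
                         z_ref: np.ndarray) -> FrameDef:
    """Hinge joint frame from two axis points, z signed to match ``z_ref``."""
    delta = pb - pa
    n = np.linalg.norm(delta)
    if n < 1e-9:
        raise DegenerateGeometryError("perturbed condyle points coincide")
    z = delta / n
    if z @ z_ref < 0:
        z = -z
    origin = 0.5 * (pa + pb)
    v = prev - origin
    y = v - (v @ z) * z
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise DegenerateGeometryError("previous origin lies on the perturbed hinge axis")
    y /= ny
    return FrameDef(origin=origin, rotation=np.column_stack([np.cross(y, z), y, z]))


def perturb_joint_parameters(model: KinematicModel, radius: float,
                             rng: np.random.Generator,
                             max_retries: int = 100) -> KinematicModel:
    """Perturb joint centers/axes and rebuild the placement frames.

    Ball-and-socket centers move inside a uniform ball; hinge condyle
    centers each move inside an independent uniform ball, keeping the
    perturbed axis inside a cylinder of the zone radius around the nominal
    axis.  The perturbed hinge z-axis keeps the nominal joint's orientation
    sign (re-deriving the medial sign from perturbed geometry could flip the
    frame by 180 degrees for axes nearly perpendicular to the medial
    direction, which no re-identification of an articular surface would
    produce).  Joints without recorded geometry (the floating base) are left
    untouched.  Draws that collapse the two hinge points (or align a ball
    joint with the sagittal normal) are resampled and counted in the
    returned model's ``mc_resample_count`` attribute.
    """
    segments = copy.deepcopy(model.segments)
    resamples = 0
    for seg in segments:
        g = seg.joint.geometry
        if not g:
            continue
        plane = PlaneDef(unit_normal=np.asarray(g["sagittal_normal"], dtype=float),
                         point_on_plane=np.asarray(g["sagittal_point"], dtype=float))
        prev = np.asarray(g["prev_origin"], dtype=float)
        for attempt in range(max_retries):
            try:
                if g["kind"] == "ball":
                    center = np.asarray(g["center"], dtype=float) + sample_uniform_ball(radius, rng)
                    frame = build_ball_frame(center, prev, plane, flip_x=g.get("flip_x", False))
                    newg = {**g, "center": center}
                elif g["kind"] == "hinge":
                    pa = np.asarray(g["condyle_a"], dtype=float) + sample_uniform_ball(radius, rng)
                    pb = np.asarray(g["condyle_b"], dtype=float) + sample_uniform_ball(radius, rng)
                    frame = _hinge_frame_aligned(pa, pb, prev,
                                                 seg.joint.frame_in_parent.rotation[:, 2])
                    newg = {**g, "condyle_a": pa, "condyle_b": pb}
                else:
                    raise InvalidInputError(f"unknown geometry kind {g['kind']!r}")
                break
            except DegenerateGeometryError:
                resamples += 1
        else:
            raise DegenerateGeometryError(
                f"could not draw a non-degenerate perturbation for joint {seg.joint.name!r}")
        seg.joint.frame_in_parent = frame
        seg.joint.geometry = newg
    out = assemble_model(segments)
    out.mc_resample_count = resamples
    return out


def run_monte_carlo(model: KinematicModel, trial: MarkerTrial, settings: IKSettings,
                    spec: PerturbationSpec, coverage_multiplier: float = 2.0,
                    baseline=None) -> MCResult:
    """Propagate one perturbation source through IK over the whole trial.

    The unperturbed model is solved once (multi-start + warm start) and its
    trajectory warm-starts every perturbed solve.  Iterations whose IK leaves
    any frame unsolved are dropped and logged, never imputed.  Per-iteration
    randomness comes from independent substreams spawned from the master
    seed, so results are bit-reproducible for a given (inputs, seed).
    """
    if baseline is None:
        baseline = solve_ik_trial(model, trial, settings)
    if not baseline.solved.all():
        raise InvalidInputError("baseline IK left frames unsolved; fix the trial first")
    q_init = baseline.trajectory.copy()
    q_init[:, baseline.dof_is_rotation] = np.deg2rad(q_init[:, baseline.dof_is_rotation])

    perturb = {"model_markers": perturb_marker_set,
               "joint_parameters": perturb_joint_parameters}[spec.target]
    streams = np.random.SeedSequence(spec.master_seed).spawn(spec.n_iterations)
    samples = []
    failures = []
    for it in range(spec.n_iterations):
        rng = np.random.default_rng(streams[it])
        try:
            pmodel = perturb(model, spec.radius, rng)
            res = solve_ik_trial(pmodel, trial, settings, q_init_trajectory=q_init)
        except (InvalidInputError, DegenerateGeometryError) as exc:
            failures.append((it, str(exc)))
            continue
        if not res.solved.all():
            failures.append((it, f"{int((~res.solved).sum())} unsolved frames"))
            continue
        samples.append(res.trajectory.T)  # (n_dof, n_frames)
    if not samples:
        raise InvalidInputError("every Monte Carlo iteration failed")
    stack = np.array(samples)
    sd = stack.std(axis=0, ddof=1) if len(samples) > 1 else np.zeros_like(stack[0])
    return MCResult(
        coordinate_names=list(model.coordinate_names),
        dof_is_rotation=model.dof_is_rotation.copy(),
        mean=stack.mean(axis=0),
        sd=sd,
        coverage=coverage_multiplier * sd,
        n_success=len(samples),
        failures=failures,
        seed=spec.master_seed,
        coverage_multiplier=coverage_multiplier,
        rate=trial.rate,
        spec=spec,
    )


def _joint_meta(joint_name: str) -> dict:
    parts = joint_name.split("_")
    if parts[0] in _LEGS:
        token = parts[-1]
        return {"leg": parts[0], "joint_kind": _TOKEN_TO_KIND.get(token, token),
                "side": {"l": "left", "r": "right"}[parts[0][1]],
                "row": {"f": "front", "m": "middle", "r": "rear"}[parts[0][0]]}
    return {"leg": None, "joint_kind": _TOKEN_TO_KIND.get(joint_name, joint_name),
            "side": None, "row": None}


def compute_snr(mc: MCResult, include_base: bool = False) -> SNRReport:
    """Per-DOF SNR = peak-to-peak mean-trajectory amplitude / max coverage.

    Translational DOFs (and, by default, the floating-base rotations) are
    not part of the joint-angle sensitivity report.  DOFs with zero noise
    power are excluded with a note rather than reported as infinite.
    """
    rows = []
    excluded = []
    base_joint = mc.coordinate_names[0].split(":")[0] if mc.coordinate_names else None
    for k, cname in enumerate(mc.coordinate_names):
        joint, dof = cname.split(":")
        if not mc.dof_is_rotation[k]:
            continue
        if joint == base_joint and not include_base:
            continue
        ps = float(np.ptp(mc.mean[k]))
        pn = float(np.max(mc.coverage[k]))
        if pn <= 0:
            excluded.append((cname, "zero noise power (Pn = 0); SNR undefined"))
            continue
        meta = _joint_meta(joint)
        rows.append({"coordinate": cname, "joint": joint, "dof": dof,
                     "Ps": ps, "Pn": pn, "snr": ps / pn, **meta})
    df = pd.DataFrame(rows).set_index("coordinate") if rows else pd.DataFrame(
        columns=["joint", "dof", "Ps", "Pn", "snr", "leg", "joint_kind", "side", "row"])
    return SNRReport(per_dof=df, excluded=excluded)


def summarize_snr(report: SNRReport) -> pd.DataFrame:
    """Group-average SNR table.

    Rows: all joints; right/left side (leg joints); front/middle/rear legs;
    then one row per joint kind averaged over the legs (or the single trunk
    joint).  Empty groups are omitted.
    """
    df = report.per_dof
    if df.empty:
        raise InvalidInputError("SNR report holds no DOFs")
    rows = []

    def add(name, sub):
        if len(sub):
            rows.append({"group": name, "n_dof": len(sub), "snr": float(sub["snr"].mean())})

    add("all joints", df)
    add("right-hand side joints", df[df["side"] == "right"])
    add("left-hand side joints", df[df["side"] == "left"])
    add("front legs joints", df[df["row"] == "front"])
    add("middle legs joints", df[df["row"] == "middle"])
    add("rear legs joints", df[df["row"] == "rear"])
    for kind in JOINT_KIND_ORDER:
        add(kind, df[df["joint_kind"] == kind])
    return pd.DataFrame(rows).set_index("group")
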