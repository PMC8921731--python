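# antkin

Whole-body kinematic modelling of ant locomotion: build a constrained
multibody model of a walking ant from fitted joint geometry, solve
marker-based inverse kinematics over a gait cycle, and quantify how
uncertainties in marker placement and joint-geometry identification
propagate into the computed joint angles.

Motion analysis at the insect scale is hard: an ant's body is a few
millimetres long, physical markers are impossible, each segment carries only
a couple of trackable landmarks, and the joint centers and axes must be
inferred from µ-CT scans of the exoskeleton.  Before drawing biological or
robotic conclusions from such a model one has to know how sensitive its
outputs are to those measurement steps.  `antkin` packages the whole chain
for biomechanists and roboticists working on hexapod locomotion.

## What it computes

* **Joint geometry** — least-squares spheres on articular-surface point
  clouds (centers of ball-and-socket joints); hinge axes through two fitted
  condyle spheres; anatomical segment frames (sagittal plane from the
  propodeal spiracles, y anterior/proximal, hinge z medial).
* **Inverse kinematics** — per frame, the bounded weighted least-squares
  problem

      min_q  Σᵢ wᵢ ‖xᵢ_obs − xᵢ_model(q)‖²    s.t. ROM limits,

  solved with an analytic geometric Jacobian (numba-accelerated),
  multi-start at the first frame and warm starts thereafter; reports per-
  frame marker RMSE and per-DOF ranges of motion.
* **Uncertainty propagation** — Monte Carlo over uniform spherical zones for
  model markers (default radius 0.4 mm) and spherical/cylindrical zones for
  joint centers/axes (default 0.2 mm); per-DOF mean trajectories θ̄(t),
  coverage intervals Δθ(t) = 2σ(t), and the sensitivity statistic
  SNR = Ps/Pn (peak-to-peak signal over maximum coverage), with group
  averages per side, leg row and joint.
* **Synthetic data** — a fully known 40-segment / 65-DOF floating-base
  hexapod with published range-of-motion limits, tripod-gait trajectories,
  rendered marker trials (C3D/TRC) and articular-surface caps, so every
  stage is testable without downloads.

## Worked example

```python
import antkin as ak

model = ak.make_synthetic_hexapod()
spec = ak.SyntheticGaitSpec(seed=7)          # 1.39 s gait cycle at 100 Hz
t, Q = ak.make_gait_trajectories(model, spec)
trial = ak.render_marker_trial(model, Q, rate=spec.rate)

result = ak.solve_ik_trial(model, trial, ak.IKSettings(seed=7))
rom = ak.range_of_motion(result)
print(f"average marker RMSE: {result.average_rmse:.2e} mm")
print(f"middle-left femur/tibia flexion range: {rom['ml_ti:flexion']:.1f} deg")

mc = ak.run_monte_carlo(
    model, trial, ak.IKSettings(seed=7, cost_tolerance=1e-6, step_tolerance=1e-8),
    ak.PerturbationSpec("model_markers", radius=0.4, n_iterations=25, master_seed=7),
    baseline=result)
print(ak.summarize_snr(ak.compute_snr(mc)).round(2).head(8).to_string())
```

prints

```
average marker RMSE: 6.67e-16 mm
middle-left femur/tibia flexion range: 33.6 deg
                        n_dof   snr
group                              
all joints                 59  0.69
right-hand side joints     26  0.79
left-hand side joints      26  0.70
front legs joints          20  0.55
middle legs joints         16  0.87
rear legs joints           16  0.87
thorax/head                 3  0.24
thorax/abdomen              3  0.23
```

The ~1e-16 mm RMSE says the solver reproduces a noiseless synthetic trial to
machine precision.  The flexion range (33.6°) is the max−min span of that
joint angle over the cycle.  The SNR table summarises the marker-placement
study: with 0.4 mm uncertainty zones on a 6.6 mm body, the group-average
SNR is below 1 — the coverage band is wider than the signal for many DOFs —
which is exactly the kind of statement the pipeline exists to make.

A command-line interface mirrors the pipeline
(`antkin simulate | prep | fit-geometry | scale | ik | mc | snr`); run
`antkin --help` for details.

## Layout

```
src/antkin/
  geometry.py     sphere/axis fitting, anatomical frames, point-cloud IO
  model.py        segments, joints, ROM, forward kinematics + Jacobian
  _fastkin.py     numba kernel (numpy fallback stays the reference)
  trial.py        MarkerTrial, filtering, resampling, gait-cycle cropping
  c3d.py, trc.py  motion-capture file formats
  modelio.py      YAML model schema
  ik.py           scaling + inverse kinematics
  montecarlo.py   perturbation sampling, MC runner, SNR
  synthetic.py    hexapod / gait / surface generators
  cli.py          click command-line interface
docs/methods.md   model assumptions, conventions, parameter rationale
```
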