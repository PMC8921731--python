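"""Shared fixtures: the synthetic hexapod and rendered gait trials.

Session-scoped because model assembly and the JIT warm-up are reused by many
tests; everything is generated programmatically from fixed seeds.
"""

import numpy as np
import pytest

import antkin as ak


@pytest.fixture(scope="session")
def hexapod():
    return ak.make_synthetic_hexapod()


@pytest.fixture(scope="session")
def gait_full(hexapod):
    """Full default gait cycle: 139 frames at 100 Hz, noiseless."""
    spec = ak.SyntheticGaitSpec()
    t, Q = ak.make_gait_trajectories(hexapod, spec)
    trial = ak.render_marker_trial(hexapod, Q, rate=spec.rate)
    return {"model": hexapod, "time": t, "Q": Q, "trial": trial, "spec": spec}


@pytest.fixture(scope="session")
def gait_mini(hexapod):
    """Short 8-frame slice of the gait for Monte Carlo-heavy tests."""
    spec = ak.SyntheticGaitSpec(duration=0.08, rate=100.0)
    t, Q = ak.make_gait_trajectories(hexapod, spec)
    trial = ak.render_marker_trial(hexapod, Q, rate=spec.rate)
    return {"model": hexapod, "time": t, "Q": Q, "trial": trial, "spec": spec}


@pytest.fixture(scope="session")
def mc_settings():
    """IK settings sized for Monte Carlo sweeps (looser termination: the
    residual landscape under mm-scale perturbation makes 1e-10 relative
    tolerances pay hundreds of extra solver iterations for micro-degree
    changes far below the coverage widths being estimated)."""
    return ak.IKSettings(seed=1, cost_tolerance=1e-6, step_tolerance=1e-8)


def random_rotation(rng):
    """Haar-ish random rotation matrix from a QR decomposition."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
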