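"""Uncertainty sampling, model perturbation and SNR reporting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import antkin as ak
from antkin.errors import InvalidParameterError
from antkin.montecarlo import MCResult, _joint_meta


class TestUniformBall:
    def test_zero_radius(self):
        assert np.array_equal(ak.sample_uniform_ball(0.0, np.random.default_rng(0)),
                              np.zeros(3))

    def test_support_bound(self):
        s = ak.sample_uniform_ball(0.4, np.random.default_rng(1), size=5000)
        assert np.linalg.norm(s, axis=1).max() <= 0.4 + 1e-12

    def test_deterministic_given_rng_state(self):
        a = ak.sample_uniform_ball(0.3, np.random.default_rng(7), size=10)
        b = ak.sample_uniform_ball(0.3, np.random.default_rng(7), size=10)
        assert np.array_equal(a, b)

    def test_negative_radius_rejected(self):
        with pytest.raises(InvalidParameterError):
            ak.sample_uniform_ball(-0.1, np.random.default_rng(0))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(radius=st.floats(min_value=0.0, max_value=10.0),
           seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_support_scales_with_radius(self, radius, seed):
        s = ak.sample_uniform_ball(radius, np.random.default_rng(seed), size=200)
        assert np.linalg.norm(s, axis=1).max() <= radius + 1e-9 * max(radius, 1.0)


class TestPerturbMarkers:
    def test_zero_radius_is_noop(self, hexapod):
        out = ak.perturb_marker_set(hexapod, 0.0, np.random.default_rng(0))
        q = np.zeros(hexapod.n_dof)
        assert np.allclose(out.marker_positions_array(q),
                           hexapod.marker_positions_array(q), atol=1e-15)

    def test_offsets_within_radius(self, hexapod):
        rng = np.random.default_rng(3)
        out = ak.perturb_marker_set(hexapod, 0.25, rng)
        for s0, s1 in zip(hexapod.segments, out.segments):
            for name in s0.markers:
                assert np.linalg.norm(s1.markers[name] - s0.markers[name]) <= 0.25 + 1e-12

    def test_same_seed_same_model(self, hexapod):
        a = ak.perturb_marker_set(hexapod, 0.4, np.random.default_rng(11))
        b = ak.perturb_marker_set(hexapod, 0.4, np.random.default_rng(11))
        assert np.array_equal(a._marker_local, b._marker_local)


class TestPerturbJoints:
    def test_zero_radius_reproduces_frames(self, hexapod):
        """Rebuilding every joint frame from unperturbed geometry must be
        the identity: the recorded primitives encode the placement exactly."""
        out = ak.perturb_joint_parameters(hexapod, 0.0, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        q = rng.uniform(-0.2, 0.2, hexapod.n_dof)
        assert np.allclose(out.marker_positions_array(q),
                           hexapod.marker_positions_array(q), atol=1e-10)

    def test_condyle_points_stay_in_cylinder(self, hexapod):
        rng = np.random.default_rng(5)
        r = 0.2
        for _ in range(50):
            out = ak.perturb_joint_parameters(hexapod, r, rng)
            for s0, s1 in zip(hexapod.segments, out.segments):
                g0, g1 = s0.joint.geometry, s1.joint.geometry
                if not g0 or g0["kind"] != "hinge":
                    continue
                for key in ("condyle_a", "condyle_b"):
                    assert np.linalg.norm(np.asarray(g1[key]) - np.asarray(g0[key])) \
                        <= r + 1e-12

    def test_axis_tilt_bounded(self, hexapod):
        """Induced tilt cannot exceed arcsin(2r/L) for condyle separation L."""
        rng = np.random.default_rng(6)
        r = 0.1
        for _ in range(30):
            out = ak.perturb_joint_parameters(hexapod, r, rng)
            for s0, s1 in zip(hexapod.segments, out.segments):
                g0, g1 = s0.joint.geometry, s1.joint.geometry
                if not g0 or g0["kind"] != "hinge":
                    continue
                a0 = np.asarray(g0["condyle_b"]) - np.asarray(g0["condyle_a"])
                a1 = np.asarray(g1["condyle_b"]) - np.asarray(g1["condyle_a"])
                L = np.linalg.norm(a0)
                tilt = np.arccos(np.clip(a0 @ a1 / (L * np.linalg.norm(a1)), -1, 1))
                assert tilt <= np.arcsin(min(1.0, 2 * r / L)) + 1e-9

    def test_hinge_z_sign_is_preserved(self, hexapod):
        rng = np.random.default_rng(8)
        out = ak.perturb_joint_parameters(hexapod, 0.2, rng)
        for s0, s1 in zip(hexapod.segments, out.segments):
            if s0.joint.joint_type != "hinge1":
                continue
            z0 = s0.joint.frame_in_parent.rotation[:, 2]
            z1 = s1.joint.frame_in_parent.rotation[:, 2]
            assert z0 @ z1 > 0


def make_mc(mean, coverage, names=None, rate=100.0):
    mean = np.atleast_2d(mean)
    coverage = np.broadcast_to(coverage, mean.shape).copy()
    n = mean.shape[0]
    names = names or [f"j{i}:flexion" for i in range(n)]
    return MCResult(
        coordinate_names=names,
        dof_is_rotation=np.ones(n, dtype=bool),
        mean=mean, sd=coverage / 2.0, coverage=coverage,
        n_success=100, failures=[], seed=0, coverage_multiplier=2.0, rate=rate)


class TestSnr:
    def test_sinusoid_closed_form(self):
        t = np.arange(100) / 100.0
        mc = make_mc(10.0 * np.sin(2 * np.pi * t), 5.0,
                     names=["base:rx", "ml_fe:flexion"],
                     )
        # first row is treated as floating base and skipped; use 2 dofs
        mc.mean = np.vstack([np.zeros(100), 10.0 * np.sin(2 * np.pi * t)])
        mc.sd = np.full((2, 100), 2.5)
        mc.coverage = np.full((2, 100), 5.0)
        mc.dof_is_rotation = np.ones(2, dtype=bool)
        rep = ak.compute_snr(mc)
        row = rep.per_dof.loc["ml_fe:flexion"]
        assert row["Ps"] == pytest.approx(20.0)
        assert row["Pn"] == pytest.approx(5.0)
        assert row["snr"] == pytest.approx(4.0)

    def test_offset_invariance(self):
        t = np.arange(100) / 100.0
        base = np.vstack([np.zeros(100), 10.0 * np.sin(2 * np.pi * t)])
        mc0 = make_mc(base, 5.0, names=["base:rx", "ml_fe:flexion"])
        mc1 = make_mc(base + 33.0, 5.0, names=["base:rx", "ml_fe:flexion"])
        s0 = ak.compute_snr(mc0).per_dof.loc["ml_fe:flexion", "snr"]
        s1 = ak.compute_snr(mc1).per_dof.loc["ml_fe:flexion", "snr"]
        assert s0 == s1

    def test_zero_noise_power_excluded_not_infinite(self):
        mc = make_mc(np.vstack([np.zeros(10), np.linspace(0, 5, 10)]), 0.0,
                     names=["base:rx", "ml_fe:flexion"])
        rep = ak.compute_snr(mc)
        assert rep.per_dof.empty
        assert any("ml_fe:flexion" in e[0] for e in rep.excluded)

    def test_coverage_is_twice_sd(self, hexapod, gait_mini, mc_settings):
        spec = ak.PerturbationSpec("model_markers", 0.2, n_iterations=6, master_seed=2)
        mc = ak.run_monte_carlo(hexapod, gait_mini["trial"], mc_settings, spec)
        assert np.allclose(mc.coverage, 2.0 * mc.sd)
        assert mc.n_success + len(mc.failures) == 6


class TestGrouping:
    def test_joint_meta(self):
        meta = _joint_meta("ml_fe")
        assert meta == {"leg": "ml", "joint_kind": "tro/fe", "side": "left",
                        "row": "middle"}
        assert _joint_meta("head")["joint_kind"] == "thorax/head"

    def test_uniform_snr_gives_uniform_groups(self):
        t = np.arange(20)
        rows = []
        for joint in ("fl_fe", "rr_ta", "head"):
            rows.append((joint, 3.0))
        mean = np.vstack([np.zeros(20)] + [np.sin(t / 3.0) * 7.5 for _ in rows])
        mc = make_mc(mean, 0.0, names=["base:rx"] + [f"{j}:flexion" for j, _ in rows])
        mc.coverage[1:] = np.ptp(mc.mean[1], axis=0) / 3.0  # snr exactly 3 everywhere
        rep = ak.compute_snr(mc)
        table = ak.summarize_snr(rep)
        assert np.allclose(table["snr"], 3.0)

    def test_mean_of_two_and_four_is_three(self):
        t = np.arange(100) / 100.0  # samples hit the sinusoid extrema exactly
        mean = np.vstack([np.zeros(100), 2 * np.sin(2 * np.pi * t), 4 * np.sin(2 * np.pi * t)])
        mc = make_mc(mean, 2.0, names=["base:rx", "fl_fe:flexion", "fr_fe:flexion"])
        table = ak.summarize_snr(ak.compute_snr(mc))
        assert table.loc["all joints", "snr"] == pytest.approx(3.0)
        assert table.loc["tro/fe", "snr"] == pytest.approx(3.0)

    def test_group_table_layout(self, hexapod, gait_mini, mc_settings):
        spec = ak.PerturbationSpec("model_markers", 0.1, n_iterations=4, master_seed=9)
        mc = ak.run_monte_carlo(hexapod, gait_mini["trial"], mc_settings, spec)
        table = ak.summarize_snr(ak.compute_snr(mc))
        assert list(table.index[:6]) == [
            "all joints", "right-hand side joints", "left-hand side joints",
            "front legs joints", "middle legs joints", "rear legs joints"]
        # eight per-joint rows as in the published summary layout
        assert len(table.index) == 6 + 8
        assert table["n_dof"].loc["fe/ti"] == 6


class TestMonteCarloRunner:
    def test_failed_iterations_logged_not_imputed(self, hexapod, gait_mini, mc_settings,
                                                  monkeypatch):
        calls = {"n": 0}
        orig = ak.perturb_marker_set

        def flaky(model, radius, rng):
            calls["n"] += 1
            if calls["n"] == 2:
                raise ak.InvalidInputError("synthetic failure")
            return orig(model, radius, rng)

        monkeypatch.setattr("antkin.montecarlo.perturb_marker_set", flaky)
        spec = ak.PerturbationSpec("model_markers", 0.1, n_iterations=4, master_seed=1)
        mc = ak.run_monte_carlo(hexapod, gait_mini["trial"], mc_settings, spec)
        assert mc.n_success == 3
        assert len(mc.failures) == 1
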