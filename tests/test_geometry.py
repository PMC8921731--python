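"""Sphere/axis fitting and anatomical coordinate-system construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

import antkin as ak
from antkin.errors import DegenerateGeometryError, InvalidInputError

from conftest import random_rotation


def octahedron():
    return np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
                    dtype=float)


class TestFitSphere:
    def test_exact_unit_sphere(self):
        f = ak.fit_sphere(octahedron())
        assert np.allclose(f.center, 0, atol=1e-12)
        assert f.radius == pytest.approx(1.0, abs=1e-12)
        assert f.rms_residual == pytest.approx(0.0, abs=1e-12)
        assert f.n_points == 6

    def test_noiseless_cap_matches_geometric_minimizer(self):
        """Algebraic fit on a partial cap equals an independent geometric
        minimizer (Nelder-Mead on sum of squared surface distances)."""
        pts = ak.make_articular_surface(ak.SurfaceCloudSpec(
            center=(1.0, 2.0, 0.5), radius=0.35, cap_half_angle_deg=60,
            n_points=200, seed=3))
        f = ak.fit_sphere(pts, refine=False)

        def geo(x):
            return np.sum((np.linalg.norm(pts - x[:3], axis=1) - x[3]) ** 2)

        ora = minimize(geo, [1.01, 1.99, 0.52, 0.33], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000}).x
        assert np.allclose(f.center, [1.0, 2.0, 0.5], atol=1e-9)
        assert f.radius == pytest.approx(0.35, abs=1e-9)
        assert np.allclose(f.center, ora[:3], atol=1e-6)
        assert f.radius == pytest.approx(ora[3], abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = ak.make_articular_surface(ak.SurfaceCloudSpec(
            radius=0.35, n_points=80, radial_noise_sd=0.004, seed=seed))
        R, t = random_rotation(rng), rng.normal(scale=5.0, size=3)
        f0 = ak.fit_sphere(pts)
        f1 = ak.fit_sphere(pts @ R.T + t)
        assert np.allclose(f1.center, R @ f0.center + t, atol=1e-8)
        assert f1.radius == pytest.approx(f0.radius, abs=1e-9)
        assert f1.rms_residual == pytest.approx(f0.rms_residual, abs=1e-9)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(cx=st.floats(-10, 10), cy=st.floats(-10, 10), cz=st.floats(-10, 10),
           radius=st.floats(0.01, 5.0), seed=st.integers(0, 2**31 - 1))
    def test_exact_cap_always_recovered(self, cx, cy, cz, radius, seed):
        """Any noiseless spherical cap yields its generating sphere."""
        pts = ak.make_articular_surface(ak.SurfaceCloudSpec(
            center=(cx, cy, cz), radius=radius, cap_half_angle_deg=70,
            n_points=60, seed=seed))
        f = ak.fit_sphere(pts)
        scale = max(1.0, abs(cx), abs(cy), abs(cz), radius)
        assert np.linalg.norm(f.center - [cx, cy, cz]) < 1e-7 * scale
        assert abs(f.radius - radius) < 1e-7 * scale

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            ak.fit_sphere(octahedron()[:3])

    def test_coplanar_cloud_rejected(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.normal(size=(30, 2)), np.zeros(30)])
        with pytest.raises(DegenerateGeometryError):
            ak.fit_sphere(pts)


class TestHingeAxis:
    def test_exact_condyles(self):
        a = octahedron() * 0.05 + [0, 0, -1]
        b = octahedron() * 0.05 + [0, 0, 1]
        h = ak.fit_hinge_axis(a, b)
        assert np.allclose(h.axis_dir, [0, 0, 1], atol=1e-12)
        assert np.allclose(h.midpoint, 0, atol=1e-12)

    def test_midpoint_arithmetic(self):
        a = octahedron() * 0.05 + [1, 0, 0]
        b = octahedron() * 0.05 + [1, 0, 0.4]
        h = ak.fit_hinge_axis(a, b)
        assert np.allclose(h.midpoint, [1, 0, 0.2], atol=1e-12)
        assert np.allclose(h.axis_dir, [0, 0, 1], atol=1e-12)

    def test_coincident_centers_rejected(self):
        a = octahedron() * 0.05
        with pytest.raises(DegenerateGeometryError):
            ak.fit_hinge_axis(a, a)


class TestSagittalPlane:
    @pytest.mark.parametrize("cl,cr,normal,psp", [
        ((-0.5, 0, 0), (0.5, 0, 0), (1, 0, 0), (0, 0, 0)),
        ((0, 1, 0), (0, 3, 0), (0, 1, 0), (0, 2, 0)),
    ])
    def test_from_spiracle_spheres(self, cl, cr, normal, psp):
        left = octahedron() * 0.05 + cl
        right = octahedron() * 0.05 + cr
        p = ak.define_sagittal_plane(left, right)
        assert np.allclose(p.unit_normal, normal, atol=1e-12)
        assert np.allclose(p.point_on_plane, psp, atol=1e-12)

    def test_rotates_with_rigid_motion(self):
        rng = np.random.default_rng(7)
        R, t = random_rotation(rng), rng.normal(size=3)
        left = octahedron() * 0.05 + [0, 1, 0]
        right = octahedron() * 0.05 + [0, 3, 0]
        p0 = ak.define_sagittal_plane(left, right)
        p1 = ak.define_sagittal_plane(left @ R.T + t, right @ R.T + t)
        assert np.allclose(p1.unit_normal, R @ p0.unit_normal, atol=1e-9)
        assert np.allclose(p1.point_on_plane, R @ p0.point_on_plane + t, atol=1e-9)


def _plane(normal, point=(0, 0, 0)):
    return ak.PlaneDef(unit_normal=np.asarray(normal, dtype=float),
                       point_on_plane=np.asarray(point, dtype=float))


def _assert_orthonormal(frame):
    R = frame.rotation
    assert np.abs(R @ R.T - np.eye(3)).max() < 1e-10
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)


class TestFrames:
    def test_thorax_frame_example(self):
        f = ak.build_thorax_frame([0, 1, 0], [0, -1, 0], _plane([1, 0, 0]))
        assert np.allclose(f.origin, 0)
        assert np.allclose(f.y, [0, 1, 0], atol=1e-12)
        _assert_orthonormal(f)

    def test_thorax_frame_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            ak.build_thorax_frame([1, 0, 0], [-1, 0, 0], _plane([1, 0, 0]))

    def test_ball_frame_example(self):
        f = ak.build_ball_frame([0, 0, 0], [0, 3, 0], _plane([1, 0, 0]))
        assert np.allclose(f.origin, 0)
        assert np.allclose(f.y, [0, 1, 0], atol=1e-12)
        _assert_orthonormal(f)

    def test_ball_frame_parallel_to_normal_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            ak.build_ball_frame([0, 0, 0], [2, 0, 0], _plane([1, 0, 0]))

    def test_hinge_frame_example(self):
        a = octahedron() * 0.05 + [0, 0, -0.2]
        b = octahedron() * 0.05 + [0, 0, 0.2]
        h = ak.fit_hinge_axis(a, b)
        f = ak.build_hinge_frame(h, [0, 2, 0], _plane([0, 0, 1], (0, 0, 5)))
        assert np.allclose(f.origin, 0, atol=1e-12)
        assert np.allclose(f.y, [0, 1, 0], atol=1e-12)
        assert np.allclose(f.z, [0, 0, 1], atol=1e-12)  # toward the plane foot
        assert np.allclose(f.x, np.cross(f.y, f.z), atol=1e-12)
        _assert_orthonormal(f)

    def test_hinge_frame_medial_sign_flips_with_side(self):
        """Mirrored joints get opposite z so both point toward the midline."""
        for side in (2.0, -2.0):
            f = ak.hinge_frame_from_centers([0, side - 0.2, 0], [0, side + 0.2, 0],
                                            [1, side, 0], _plane([0, 1, 0]))
            assert np.allclose(f.z, [0, -np.sign(side), 0], atol=1e-12)

    def test_hinge_frame_midline_fallback_uses_plane_normal(self):
        """A joint lying on the sagittal plane orients z along the normal."""
        f = ak.hinge_frame_from_centers([0, -0.2, 0], [0, 0.2, 0], [1, 0, 0],
                                        _plane([0, 1, 0]))
        assert np.allclose(f.z, [0, 1, 0], atol=1e-12)

    def test_hinge_frame_prev_origin_on_axis_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            ak.hinge_frame_from_centers([0, 0, -1], [0, 0, 1], [0, 0, 0.5],
                                        _plane([1, 0, 0], (3, 0, 0)))

    @pytest.mark.parametrize("builder", ["thorax", "ball", "hinge"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equivariance_under_rigid_motion(self, builder, seed):
        rng = np.random.default_rng(seed)
        R, t = random_rotation(rng), rng.normal(scale=3.0, size=3)
        plane = _plane([1, 0, 0], (0.3, -0.2, 0.1))
        if builder == "thorax":
            f0 = ak.build_thorax_frame([0, 1, 0.2], [0.1, -1, 0], plane)
            f1 = ak.build_thorax_frame(R @ [0, 1, 0.2] + t, R @ [0.1, -1, 0] + t,
                                       _plane(R @ plane.unit_normal, R @ plane.point_on_plane + t))
        elif builder == "ball":
            f0 = ak.build_ball_frame([0.2, 0.1, 0], [0.3, 3, 0.5], plane)
            f1 = ak.build_ball_frame(R @ [0.2, 0.1, 0] + t, R @ [0.3, 3, 0.5] + t,
                                     _plane(R @ plane.unit_normal, R @ plane.point_on_plane + t))
        else:
            f0 = ak.hinge_frame_from_centers([0, 0.5, -0.2], [0.05, 0.5, 0.2], [1, 0.4, 0], plane)
            f1 = ak.hinge_frame_from_centers(
                R @ [0, 0.5, -0.2] + t, R @ [0.05, 0.5, 0.2] + t, R @ [1, 0.4, 0] + t,
                _plane(R @ plane.unit_normal, R @ plane.point_on_plane + t))
        _assert_orthonormal(f1)
        assert np.allclose(f1.origin, R @ f0.origin + t, atol=1e-10)
        assert np.allclose(f1.rotation, R @ f0.rotation, atol=1e-10)


class TestPointCloudIO:
    def test_reads_xyz_text(self, tmp_path):
        pts = octahedron()
        p = tmp_path / "cloud.xyz"
        p.write_text("# comment\n" + "\n".join(f"{x}, {y}, {z}" for x, y, z in pts))
        assert np.allclose(ak.read_point_cloud(p), pts)
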