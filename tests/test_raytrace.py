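import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corneatilt.exceptions import RayTraceError, TotalInternalReflectionError
from corneatilt.geometry import (
    ConicoidSurface,
    angle_between_axes,
    rotation_from_angles,
)
from corneatilt.raytrace import (
    CornealModel,
    Ray,
    axial_crossing_distance,
    central_ray_deviation,
    estimate_optical_axis,
    intersect,
    refract,
    trace_through_cornea,
)
from corneatilt.synthetic import CorneaSpec, make_cornea

Z = np.array([0.0, 0.0, 1.0])


def paraxial_back_focal_distance(model, y0_mm=0.1):
    """Independent reduced-angle paraxial trace of the two-surface system."""
    r1 = model.anterior.apex_radius_x * 1e-3
    r2 = model.posterior.apex_radius_x * 1e-3
    t = model.posterior.apex_offset[2] * 1e-3
    p1 = (model.n_cornea - model.n_air) / r1
    p2 = (model.n_aqueous - model.n_cornea) / r2
    w = -y0_mm * 1e-3 * p1
    y = y0_mm * 1e-3 + (t / model.n_cornea) * w
    w = w - y * p2
    return -y / (w / model.n_aqueous) * 1e3  # mm past the posterior vertex


class TestRefract:
    def test_no_index_step_leaves_direction(self, rng):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        np.testing.assert_allclose(refract(d, n, 1.4, 1.4), d, atol=1e-12)

    def test_normal_incidence_unchanged(self):
        np.testing.assert_allclose(refract(Z, Z, 1.0, 1.376), Z, atol=1e-12)
        np.testing.assert_allclose(refract(Z, -Z, 1.0, 1.376), Z, atol=1e-12)

    def test_45_degree_incidence_into_cornea(self):
        # scalar Snell: sin(t) = sin(45)/1.376 -> t = 30.923 deg in-plane
        d = np.array([1.0, 0.0, 1.0]) / math.sqrt(2)
        t = refract(d, Z, 1.0, 1.376)
        theta_t = math.asin(math.sin(math.radians(45)) / 1.376)
        np.testing.assert_allclose(
            t, [math.sin(theta_t), 0.0, math.cos(theta_t)], atol=1e-9
        )

    def test_total_internal_reflection(self):
        d = np.array([math.sin(math.radians(60)), 0, math.cos(math.radians(60))])
        with pytest.raises(TotalInternalReflectionError):
            refract(d, Z, 1.376, 1.0)

    @given(data=st.data())
    @settings(max_examples=200, derandomize=True)
    def test_snell_invariant_and_plane_of_incidence(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        n1, n2 = rng.uniform(1.0, 1.8, 2)
        try:
            t = refract(d, n, n1, n2)
        except TotalInternalReflectionError:
            assert n1 > n2
            return
        sin_i = np.linalg.norm(np.cross(d, n))
        sin_t = np.linalg.norm(np.cross(t, n))
        assert abs(n1 * sin_i - n2 * sin_t) < 1e-12
        assert abs(np.dot(t, np.cross(d, n))) < 1e-12  # stays in incidence plane
        assert abs(np.linalg.norm(t) - 1.0) < 1e-12


class TestIntersect:
    def test_axial_ray_hits_apex(self):
        surface = ConicoidSurface.symmetric(7.8, 0.0)
        p = intersect(Ray([0, 0, -10], Z), surface)
        np.testing.assert_allclose(p, [0, 0, 0], atol=1e-12)

    def test_axial_ray_hits_offset_plane(self):
        plane = ConicoidSurface.symmetric(1e9, 0.0, apex_z=0.5)
        p = intersect(Ray([0, 0, -10], Z), plane)
        assert p[2] == pytest.approx(0.5, abs=1e-9)

    def test_oblique_ray_point_on_sphere(self):
        surface = ConicoidSurface.symmetric(7.8, 0.0)
        d = np.array([0.1, -0.05, 1.0])
        d /= np.linalg.norm(d)
        p = intersect(Ray([0.5, 0.3, -5.0], d), surface)
        # sphere of radius 7.8 centred at (0, 0, 7.8)
        assert p[0] ** 2 + p[1] ** 2 + (p[2] - 7.8) ** 2 == pytest.approx(
            7.8**2, abs=1e-9
        )

    def test_miss_raises(self):
        surface = ConicoidSurface.symmetric(7.8, 0.0)
        with pytest.raises(RayTraceError):
            intersect(Ray([20.0, 0, -10], Z), surface)


class TestTraceThroughCornea:
    def test_axial_ray_undeviated_through_symmetric_model(self, gullstrand_model):
        out = trace_through_cornea(gullstrand_model, Ray([0, 0, -10], Z))
        np.testing.assert_allclose(out.direction, Z, atol=1e-12)
        np.testing.assert_allclose(out.origin[:2], [0, 0], atol=1e-12)

    def test_exit_directions_unit_length(self, gullstrand_model, rng):
        for _ in range(100):
            x, y = rng.uniform(-1.5, 1.5, 2)
            out = trace_through_cornea(gullstrand_model, Ray([x, y, -10], Z))
            assert abs(np.linalg.norm(out.direction) - 1.0) < 1e-12

    def test_paraxial_bundle_focuses_at_gullstrand_distance(self, gullstrand_model):
        bfd = paraxial_back_focal_distance(gullstrand_model)
        axis = Ray([0.0, 0.0, 0.0], Z)
        for h in (0.05, 0.1, 0.2, -0.15):
            out = trace_through_cornea(gullstrand_model, Ray([h, 0, -10], Z))
            crossing = axial_crossing_distance(out, axis)
            assert crossing == pytest.approx(bfd, rel=0.01)

    def test_reversed_exit_ray_traces_back(self, gullstrand_model, rng):
        m = gullstrand_model
        for _ in range(10):
            x, y = rng.uniform(-1.0, 1.0, 2)
            ray = Ray([x, y, -10.0], Z)
            out = trace_through_cornea(m, ray)
            rev = Ray(out.point(3.0), -out.direction)
            p2 = intersect(rev, m.posterior)
            d2 = refract(rev.direction, m.posterior.normal(p2[0], p2[1]),
                         m.n_aqueous, m.n_cornea)
            p1 = intersect(Ray(p2, d2), m.anterior)
            d1 = refract(d2, m.anterior.normal(p1[0], p1[1]), m.n_cornea, m.n_air)
            np.testing.assert_allclose(d1, -ray.direction, atol=1e-8)


class TestAxialCrossing:
    def test_parallel_rays_cross_at_infinity(self):
        assert axial_crossing_distance(
            Ray([1, 0, 0], Z), Ray([0, 0, 0], Z)
        ) == math.inf

    @pytest.mark.parametrize("phi_deg", [2.0, 10.0, 30.0])
    def test_planar_trigonometry_oracle(self, phi_deg):
        phi = math.radians(phi_deg)
        exit_ray = Ray([1.0, 0, 0], [-math.sin(phi), 0.0, math.cos(phi)])
        axis = Ray([0.0, 0.0, 0.0], Z)
        assert axial_crossing_distance(exit_ray, axis) == pytest.approx(
            1.0 / math.tan(phi), abs=1e-12
        )

    def test_invariant_under_scene_rotation(self):
        d = np.array([-0.1, 0.05, 0.99])
        exit_ray = Ray([1.2, -0.3, 0.5], d / np.linalg.norm(d))
        axis = Ray([0.0, 0.0, 0.0], Z)
        d0 = axial_crossing_distance(exit_ray, axis)
        rot = rotation_from_angles(17.0, -24.0, pivot=(0.3, 0.1, -0.5))
        r_exit = Ray(rot.apply(exit_ray.origin), rot.apply_to_direction(exit_ray.direction))
        r_axis = Ray(rot.apply(axis.origin), rot.apply_to_direction(axis.direction))
        assert axial_crossing_distance(r_exit, r_axis) == pytest.approx(d0, abs=1e-10)


class TestCentralRayDeviation:
    def test_zero_for_untilted_symmetric_model(self, gullstrand_model):
        res = central_ray_deviation(gullstrand_model, rotation_from_angles(0, 0))
        np.testing.assert_allclose(res, [0.0, 0.0], atol=1e-10)

    def test_inverse_rotation_nulls_generated_tilt(self):
        spec = CorneaSpec(tilt_x_deg=5.0, tilt_y_deg=0.0)
        ant = ConicoidSurface.symmetric(spec.anterior_radius, spec.anterior_q)
        post = ConicoidSurface.symmetric(
            spec.posterior_radius, spec.posterior_q, apex_z=spec.central_thickness
        )
        from corneatilt.geometry import RotatedSurface

        truth = rotation_from_angles(5.0, 0.0)
        tilted = CornealModel(
            RotatedSurface(ant, truth), RotatedSurface(post, truth)
        )
        res = central_ray_deviation(tilted, rotation_from_angles(-5.0, 0.0))
        assert np.linalg.norm(res) < 1e-6

    def test_residual_monotone_near_optimum(self, gullstrand_model):
        norms = [
            np.linalg.norm(
                central_ray_deviation(gullstrand_model, rotation_from_angles(a, 0.0))
            )
            for a in np.linspace(0.0, 2.0, 9)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(norms, norms[1:]))


class TestEstimateOpticalAxis:
    def test_untilted_cornea_null(self):
        ant, post, _ = make_cornea(CorneaSpec(seed=4))
        result = estimate_optical_axis(ant, post)
        assert result.angle_alpha_deg < 0.05
        assert result.converged

    def test_recovers_composed_tilt(self):
        ant, post, truth = make_cornea(CorneaSpec(tilt_x_deg=3.0, tilt_y_deg=4.0, seed=1))
        result = estimate_optical_axis(ant, post)
        true_angle = angle_between_axes(truth.apply_to_direction(Z), Z)
        assert true_angle == pytest.approx(
            math.degrees(math.acos(math.cos(math.radians(3)) * math.cos(math.radians(4))))
        )
        assert result.angle_alpha_deg == pytest.approx(true_angle, abs=0.1)
        assert result.converged

    def test_recovery_with_elevation_noise(self):
        errors = []
        for seed in range(3):
            ant, post, truth = make_cornea(
                CorneaSpec(tilt_x_deg=3.0, tilt_y_deg=4.0, noise_sd_um=2.0, seed=seed)
            )
            result = estimate_optical_axis(ant, post)
            true_angle = angle_between_axes(truth.apply_to_direction(Z), Z)
            errors.append(abs(result.angle_alpha_deg - true_angle))
        assert max(errors) < 0.5

    def test_estimate_stable_under_basis_order_change(self):
        from corneatilt.raytrace import TiltOptions

        ant, post, _ = make_cornea(CorneaSpec(tilt_x_deg=4.0, tilt_y_deg=-2.0, seed=9))
        a1 = estimate_optical_axis(ant, post, TiltOptions(basis_order=8)).angle_alpha_deg
        a2 = estimate_optical_axis(ant, post, TiltOptions(basis_order=10)).angle_alpha_deg
        assert abs(a1 - a2) < 0.05

    def test_result_invariants(self):
        ant, post, _ = make_cornea(CorneaSpec(tilt_x_deg=2.0, tilt_y_deg=1.0, seed=2))
        result = estimate_optical_axis(ant, post)
        assert result.angle_alpha_deg == pytest.approx(
            angle_between_axes(result.optical_axis, Z), abs=1e-9
        )
        assert result.residual_deviation >= 0.0
        payload = result.to_json_dict()
        assert set(payload) >= {
            "angle_alpha_deg", "optical_axis", "residual_deviation",
            "iterations", "converged",
        }
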