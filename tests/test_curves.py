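"""Curve library, moving frames, projection and invariant transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from curvetrace.curves import (
    J,
    ParametricCurve,
    SingularPointError,
    affine_transform,
    curve_from_config,
    frame_at,
    make_named_curve,
    project_to_curve,
    to_moving_frame,
    NAMED_CURVES,
)
from .conftest import random_rigid_motion


def ellipse_curvature(a, b, p):
    """Closed-form |curvature| of (a sin p, b cos p)."""
    return a * b / (a**2 * np.cos(p) ** 2 + b**2 * np.sin(p) ** 2) ** 1.5


class TestNamedCurves:
    @pytest.mark.parametrize("name", NAMED_CURVES)
    def test_analytic_derivatives_match_finite_differences(self, name):
        curve = make_named_curve(name)
        h = 1e-5
        lo, hi = curve.domain
        p = np.linspace(lo + 0.05, hi - 0.05, 37)
        fd1 = (curve.position(p + h) - curve.position(p - h)) / (2 * h)
        fd2 = (
            curve.position(p + h) - 2 * curve.position(p) + curve.position(p - h)
        ) / h**2
        scale1 = np.abs(curve.first_derivative(p)).max()
        scale2 = np.abs(curve.second_derivative(p)).max()
        assert np.abs(curve.first_derivative(p) - fd1).max() < 1e-6 * max(scale1, 1)
        assert np.abs(curve.second_derivative(p) - fd2).max() < 1e-4 * max(scale2, 1)

    @pytest.mark.parametrize(
        "name", ["figure_eight", "affine_eight_c1", "quadrifolium_c2", "ellipse_c3"]
    )
    def test_periodicity(self, name):
        curve = make_named_curve(name)
        p = np.linspace(0, 2 * np.pi, 11)
        assert np.abs(
            curve.position(p) - curve.position(p + curve.period)
        ).max() < 1e-12

    def test_printed_points(self, figure_eight, ellipse):
        # figure of eight passes through (0, 0.1) at p = pi/2
        assert np.allclose(figure_eight.position(np.pi / 2), [0.0, 0.1])
        # ellipse passes through (0.6, 0) at p = pi/2
        assert np.allclose(ellipse.position(np.pi / 2), [0.6, 0.0])

    def test_speed_scaled_eight_same_point_set(self, figure_eight):
        # c_gen(p) = c(n p): the same image traversed n times faster, so
        # matched dense samplings coincide point-for-point (Hausdorff 0).
        fast = make_named_curve("speed_scaled_eight", n=2)
        p = np.linspace(0, 2 * np.pi, 20001)
        assert np.abs(fast.position(p / 2) - figure_eight.position(p)).max() < 1e-12
        assert abs(fast.period - np.pi) < 1e-15

    def test_unknown_name_and_bad_factor(self):
        with pytest.raises(ValueError):
            make_named_curve("lemniscate")
        with pytest.raises(ValueError):
            make_named_curve("speed_scaled_eight", n=0)

    def test_from_config_affine(self, figure_eight):
        cfg = {
            "name": "figure_eight",
            "params": {"A": [[2.1, -0.7], [3.5, 2.1]], "d": [0.0, 0.0]},
        }
        built = curve_from_config(cfg)
        c1 = make_named_curve("affine_eight_c1")
        p = np.linspace(0, 2 * np.pi, 101)
        assert np.abs(built.position(p) - c1.position(p)).max() < 1e-12


class TestFrameAt:
    def test_ellipse_curvature_closed_form(self, ellipse):
        rng = np.random.default_rng(0)
        for p in rng.uniform(0, 2 * np.pi, 1000):
            mu = frame_at(ellipse, p).mu
            assert abs(abs(mu) - ellipse_curvature(0.6, 0.2, p)) < 1e-9

    def test_figure_eight_inflection_and_peak(self, figure_eight):
        assert abs(frame_at(figure_eight, 0.0).mu) < 1e-12
        assert abs(abs(frame_at(figure_eight, np.pi / 2).mu) - 10.0) < 1e-9

    def test_circle_curvature_any_radius(self):
        R = 0.35

        def pos(p):
            return np.stack([R * np.cos(p), R * np.sin(p)], axis=-1)

        circle = ParametricCurve.from_position(pos)
        for p in (0.0, 1.0, 2.5, 5.0):
            assert abs(abs(frame_at(circle, p).mu) - 1.0 / R) < 1e-4

    @given(
        name=st.sampled_from(["figure_eight", "quadrifolium_c2", "ellipse_c3"]),
        p=st.floats(0.05, 2 * np.pi - 0.05),
    )
    @settings(max_examples=200, deadline=None)
    def test_frame_orthonormal_and_oriented(self, name, p):
        frame = frame_at(make_named_curve(name), p)
        assert np.abs(frame.M.T @ frame.M - np.eye(2)).max() < 1e-12
        assert abs(np.linalg.det(frame.M) - 1.0) < 1e-12
        assert np.allclose(frame.n, J @ frame.t)

    def test_singular_point_raises(self):
        cusp = ParametricCurve(
            lambda p: np.stack([p**3, p**2], axis=-1),
            lambda p: np.stack([3 * p**2, 2 * p], axis=-1),
            lambda p: np.stack([6 * p, 2 * np.ones_like(p)], axis=-1),
            periodic=False, period=None, domain=(-1.0, 1.0),
        )
        with pytest.raises(SingularPointError):
            frame_at(cusp, 0.0)


class TestProjection:
    def test_on_curve_point_is_fixed(self, figure_eight):
        p0 = 1.3
        proj = project_to_curve(figure_eight, figure_eight.position(p0), p0)
        assert abs(proj.p_star - p0) < 1e-8
        assert abs(proj.e) < 1e-9
        assert proj.distance < 1e-9
        assert proj.interior

    @pytest.mark.parametrize("d", [0.003, -0.003])
    def test_normal_offset_recovers_signed_error(self, ellipse, d):
        p0 = 1.0
        frame = frame_at(ellipse, p0)
        r = ellipse.position(p0) + d * frame.n
        proj = project_to_curve(ellipse, r, p0)
        assert abs(proj.e - d) < 1e-6
        assert abs(proj.distance - abs(d)) < 1e-9

    def test_boundary_minimizer_flagged(self, figure_eight):
        # query far along the tangent: true minimizer outside the interval
        p0 = 0.0
        frame = frame_at(figure_eight, p0)
        r = figure_eight.position(p0) + 0.3 * frame.t
        proj = project_to_curve(figure_eight, r, p0, half_width=0.05)
        assert not proj.interior

    def test_interior_orthogonality_against_grid_oracle(self, figure_eight):
        rng = np.random.default_rng(3)
        for _ in range(25):
            p_prev = rng.uniform(0, 2 * np.pi)
            r = figure_eight.position(p_prev) + rng.normal(0, 0.004, 2)
            proj = project_to_curve(figure_eight, r, p_prev)
            grid = np.linspace(p_prev - np.pi / 4, p_prev + np.pi / 4, 200001)
            d2 = ((figure_eight.position(grid) - r) ** 2).sum(-1)
            p_grid = grid[np.argmin(d2)]
            assert abs(proj.p_star - p_grid) < 2 * (grid[1] - grid[0])
            if proj.interior:
                frame = frame_at(figure_eight, proj.p_star)
                delta = r - figure_eight.position(proj.p_star)
                assert abs(frame.t @ delta) <= 1e-6 * np.linalg.norm(delta) + 1e-9

    def test_distance_equals_abs_error_when_interior(self, ellipse):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p_prev = rng.uniform(0, 2 * np.pi)
            r = ellipse.position(p_prev) + rng.normal(0, 0.002, 2)
            proj = project_to_curve(ellipse, r, p_prev)
            if proj.interior:
                assert abs(proj.distance - abs(proj.e)) < 1e-9


class TestMovingFrameTransform:
    def test_pure_tangential_and_normal_motion(self, figure_eight):
        p0 = 0.8
        frame = frame_at(figure_eight, p0)
        r = figure_eight.position(p0)
        proj = project_to_curve(figure_eight, r, p0)
        v = 0.27
        obs_t = to_moving_frame(figure_eight, r, v * frame.t, proj)
        assert np.allclose(obs_t.rdot_moving, [v, 0.0], atol=1e-8)
        obs_n = to_moving_frame(figure_eight, r, v * frame.n, proj)
        assert np.allclose(obs_n.rdot_moving, [0.0, v], atol=1e-8)

    def test_rigid_motion_invariance(self, figure_eight):
        rng = np.random.default_rng(5)
        p_prev = 1.1
        r = figure_eight.position(p_prev) + np.array([0.002, -0.001])
        rdot = np.array([0.2, 0.05])
        proj = project_to_curve(figure_eight, r, p_prev)
        obs = to_moving_frame(figure_eight, r, rdot, proj)
        for _ in range(100):
            R, d = random_rigid_motion(rng)
            moved = affine_transform(figure_eight, R, d)
            proj2 = project_to_curve(moved, R @ r + d, p_prev)
            obs2 = to_moving_frame(moved, R @ r + d, R @ rdot, proj2)
            assert abs(obs2.e - obs.e) < 1e-8
            assert abs(obs2.mu - obs.mu) < 1e-8
            assert abs(obs2.p_star - obs.p_star) < 1e-8
            assert np.abs(obs2.rdot_moving - obs.rdot_moving).max() < 1e-8


class TestAffineTransform:
    def test_identity(self, figure_eight):
        same = affine_transform(figure_eight, np.eye(2), np.zeros(2))
        p = np.linspace(0, 2 * np.pi, 50)
        assert np.abs(same.position(p) - figure_eight.position(p)).max() == 0.0

    def test_matches_printed_c1(self, figure_eight):
        A = np.array([[2.1, -0.7], [3.5, 2.1]])
        built = affine_transform(figure_eight, A, np.zeros(2))
        c1 = make_named_curve("affine_eight_c1")
        p = np.linspace(0, 2 * np.pi, 101)
        assert np.abs(built.position(p) - c1.position(p)).max() < 1e-12

    def test_rotation_preserves_curvature_magnitude(self, ellipse):
        rng = np.random.default_rng(6)
        R, _ = random_rigid_motion(rng)
        rotated = affine_transform(ellipse, R, np.zeros(2))
        for p in rng.uniform(0, 2 * np.pi, 20):
            assert abs(
                abs(frame_at(rotated, p).mu) - abs(frame_at(ellipse, p).mu)
            ) < 1e-9

    def test_singular_matrix_rejected(self, figure_eight):
        with pytest.raises(ValueError):
            affine_transform(figure_eight, np.zeros((2, 2)), np.zeros(2))
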