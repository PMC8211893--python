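"""Registration: rigid ICP, currents metric, flow gradient, Jacobian markers."""

import numpy as np
import pytest

from ccshape import geometry
from ccshape.lddmm import (RegistrationConfig, _energy_and_grad, _make_objective,
                           currents_inner, currents_mismatch, currents_norm_sq,
                           integrate_flow_and_jacobian, lddmm_match,
                           propagate_jacobian, register_curve, rigid_align,
                           _flow_forward)


def circle(k=60, r=20.0, center=(0.0, 0.0)):
    th = np.linspace(0, -2 * np.pi, k, endpoint=False)  # clockwise, y-up
    return center + r * np.stack([np.cos(th), np.sin(th)], axis=1)


class TestRigidAlign:
    def test_exact_recovery_of_rigid_motion(self, template50):
        theta, trans = np.deg2rad(10.0), np.array([3.0, -2.0])
        target = geometry.apply_rigid(template50.points, theta, trans)
        rigid, aligned = rigid_align(target, template50.points)
        assert np.max(np.linalg.norm(aligned - template50.points, axis=1)) < 1e-6

    def test_identity_gives_zero_transform(self, template50):
        rigid, _ = rigid_align(template50.points.copy(), template50.points)
        assert abs(rigid.theta) < 1e-9
        assert np.linalg.norm(rigid.translation) < 1e-9

    def test_scaling_residual_remains(self, template50):
        c = template50.points.mean(axis=0)
        target = c + (template50.points - c) * 1.2
        _, aligned = rigid_align(target, template50.points)
        from scipy.spatial import cKDTree

        d = cKDTree(template50.points).query(aligned)[0].mean()
        radius = np.linalg.norm(template50.points - c, axis=1).mean()
        assert abs(d - 0.2 * radius) <= 0.25 * 0.2 * radius

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            rigid_align(circle(5), circle(5))


class TestCurrents:
    def test_identical_curves_zero(self):
        a = circle()
        assert currents_mismatch(a, a, 5.0) == pytest.approx(0.0, abs=1e-12)

    def test_reversed_orientation_is_four_norms(self):
        a = circle(40)
        rev = a[::-1].copy()
        m = currents_mismatch(a, rev, 6.0)
        # independent double-sum oracle for the norm
        c, tau = (a + np.roll(a, -1, axis=0)) / 2, np.roll(a, -1, axis=0) - a
        norm = sum(
            (tau[i] @ tau[j]) * np.exp(-np.sum((c[i] - c[j]) ** 2) / 36.0)
            for i in range(40) for j in range(40))
        assert m == pytest.approx(4 * norm, rel=1e-9)

    def test_far_separated_curves(self):
        a = circle(30)
        b = circle(30, center=(500.0, 0.0))
        m = currents_mismatch(a, b, 4.0)
        expected = currents_norm_sq(a, 4.0) + currents_norm_sq(b, 4.0)
        assert m == pytest.approx(expected, rel=1e-6)
        assert abs(currents_inner(a, b, 4.0)) < 1e-10

    def test_tiny_curves_rejected(self):
        with pytest.raises(ValueError):
            currents_mismatch(circle(2), circle(10), 4.0)


class TestGradient:
    def test_adjoint_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        x0 = circle(12, r=8.0)
        target = circle(12, r=9.0)
        alpha = rng.normal(0, 0.02, (5, 12, 2))
        e0, grad, _, _ = _energy_and_grad(x0, alpha, target, 4.0, 2.0, 7.0)
        h = 1e-6
        for idx in [(0, 0, 0), (2, 5, 1), (4, 11, 0)]:
            pert = alpha.copy()
            pert[idx] += h
            e1, _, _, _ = _energy_and_grad(x0, pert, target, 4.0, 2.0, 7.0)
            fd = (e1 - e0) / h
            assert grad[idx] == pytest.approx(fd, rel=2e-4, abs=1e-8)

    def test_numba_and_numpy_objectives_agree(self):
        rng = np.random.default_rng(4)
        x0 = circle(15, r=10.0)
        target = circle(15, r=11.0)
        alpha = rng.normal(0, 0.02, (6, 15, 2))
        e1, g1, p1, m1 = _energy_and_grad(x0, alpha, target, 5.0, 2.5, 3.0)
        _, e_grad = _make_objective(x0, target, 5.0, 2.5, 3.0)
        e2, g2, p2, m2 = e_grad(alpha)
        assert e1 == pytest.approx(e2, rel=1e-9)
        assert np.allclose(g1, g2, atol=1e-10)
        assert np.allclose(p1, p2, atol=1e-10)


class TestJacobian:
    def test_zero_momenta_identity(self, template50):
        T = 8
        alpha = np.zeros((T, template50.k, 2))
        xs, _, _ = _flow_forward(template50.points, alpha, 10.0)
        D, markers = propagate_jacobian(xs, alpha, template50.points, 10.0)
        assert np.allclose(markers, 1.0)
        assert np.allclose(D, np.eye(2))

    def test_linear_velocity_closed_form(self):
        """Constant v(x) = A x over unit time: D = expm(A), det D = exp(tr A)."""
        A = np.array([[0.05, 0.02], [0.01, -0.03]])
        pts = circle(10, r=5.0)
        v_fn = lambda t, x: x @ A.T
        g_fn = lambda t, x: np.tile(A, (len(x), 1, 1))
        _, D = integrate_flow_and_jacobian(v_fn, g_fn, pts, n_steps=50)
        det = np.linalg.det(D)
        assert np.allclose(det, np.exp(np.trace(A)), atol=1e-4)

    def test_cocycle_property(self):
        """The Jacobian of a two-leg flow is the product of the legs'."""
        A1 = np.array([[0.04, -0.01], [0.02, 0.01]])
        A2 = np.array([[-0.02, 0.03], [0.0, 0.05]])

        def v(t, x):
            return x @ (A1 if t < 0.5 else A2).T

        def g(t, x):
            return np.tile(A1 if t < 0.5 else A2, (len(x), 1, 1))

        pts = circle(8, r=4.0)
        _, D_full = integrate_flow_and_jacobian(v, g, pts, n_steps=40)
        # each leg holds its field for half the composite duration, so the
        # separate integrations use the half-strength field over unit time
        # (identical Euler steps to the composite's 20-step halves)
        xh, D1h = integrate_flow_and_jacobian(
            lambda t, x: 0.5 * (x @ A1.T), lambda t, x: np.tile(0.5 * A1, (len(x), 1, 1)), pts, 20)
        _, D2h = integrate_flow_and_jacobian(
            lambda t, x: 0.5 * (x @ A2.T), lambda t, x: np.tile(0.5 * A2, (len(x), 1, 1)), xh, 20)
        assert np.allclose(D2h @ D1h, D_full, atol=1e-6)


class TestMatch:
    def test_identity_markers_near_one(self, template50):
        res = lddmm_match(template50, template50.points.copy())
        assert res.converged
        assert np.all((res.markers > 0.99) & (res.markers < 1.01))
        assert np.allclose(res.markers, np.linalg.det(res.jacobians))

    def test_energy_monotone_on_accepted_steps(self, template50, fast_reg):
        c = template50.points.mean(axis=0)
        res = lddmm_match(template50, c + (template50.points - c) * 1.05, fast_reg)
        assert np.all(np.diff(res.energy_trace) <= 1e-9)
        assert res.final_energy <= res.energy_trace[0]

    def test_localized_dent_yields_local_contraction(self, template50, fast_reg):
        from ccshape.synthetic import _effect_window

        cum = geometry.cumulative_arclength(template50.points)
        frac = cum[:-1] / cum[-1]
        win = _effect_window(frac, (0.10, 0.18))
        dent_center = template50.points[np.argmax(win)]
        target = template50.points - 1.0 * win[:, None] * geometry.outward_normals(template50.points)
        res = lddmm_match(template50, target, fast_reg)
        k_min = int(np.argmin(res.markers))
        assert res.markers[k_min] < 1.0
        # strongest contraction within sigma_V (spatially) of the dent centre:
        # for the two-walled CC band it may sit on the facing inner wall
        assert np.linalg.norm(template50.points[k_min] - dent_center) <= res.config.sigma_V

    def test_circle_dent_minimum_on_the_dent_arc(self):
        pts = circle(80, r=20.0)
        cum = geometry.cumulative_arclength(pts)
        frac = cum[:-1] / cum[-1]
        from ccshape.synthetic import _effect_window

        win = _effect_window(frac, (0.30, 0.45))
        target = pts - 1.5 * win[:, None] * geometry.outward_normals(pts)
        cfg = RegistrationConfig(sigma_V=6.0, max_iters=200)
        res = lddmm_match(pts, target, cfg)
        k_min = int(np.argmin(res.markers))
        arc = cum[:-1]
        d = geometry.cyclic_interval_distance(
            np.array([arc[k_min]]), (0.30 * cum[-1], 0.45 * cum[-1]), cum[-1])[0]
        assert res.markers[k_min] < 1.0
        assert d <= cfg.sigma_V

    def test_equivariance_under_common_rotation(self, template50, fast_reg):
        c = template50.points.mean(axis=0)
        target = c + (template50.points - c) * 1.05
        res1 = lddmm_match(template50, target, fast_reg)
        theta, trans = np.deg2rad(23.0), np.array([5.0, -7.0])
        tpl_rot = geometry.apply_rigid(template50.points, theta, trans)
        tgt_rot = geometry.apply_rigid(target, theta, trans)
        res2 = lddmm_match(tpl_rot, tgt_rot, fast_reg)
        assert np.allclose(res1.markers, res2.markers, atol=1e-6)

    def test_markers_match_finite_difference_area_oracle(self, template50, fast_reg):
        """Flow a tiny square at each template point through the fitted flow;
        its area ratio must agree with det D."""
        c = template50.points.mean(axis=0)
        res = lddmm_match(template50, c + (template50.points - c) * 1.08, fast_reg)
        from ccshape.lddmm import _kernel_velocity_and_grad

        h = 1e-3
        T = res.momenta.shape[0]
        xs, _, _ = _flow_forward(template50.points, res.momenta, res.config.sigma_V)
        offsets = np.array([[-h, -h], [h, -h], [h, h], [-h, h]]) / 2
        corners = (template50.points[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
        x = corners.copy()
        for t in range(T):
            v, _ = _kernel_velocity_and_grad(xs[t], res.momenta[t], x, res.config.sigma_V)
            x = x + v / T
        quads = x.reshape(-1, 4, 2)
        ratios = np.array([geometry.polygon_area(q) for q in quads]) / (h * h)
        assert np.allclose(ratios, res.markers, rtol=0.02)

    def test_nonpositive_marker_raises(self):
        # a violently compressive hand-built flow must be rejected
        pts = circle(12, r=3.0)
        alpha = np.full((5, 12, 2), 0.0)
        alpha[:, :, 0] = -pts[:, 0] * 5.0  # strong inward crush
        xs, _, _ = _flow_forward(pts, alpha, 2.0)
        with pytest.raises(RuntimeError, match="marker"):
            propagate_jacobian(xs, alpha, pts, 2.0)

    def test_register_curve_end_to_end(self, small_curves, template50, fast_reg):
        res = register_curve(small_curves[0], template50, fast_reg)
        assert np.all(res.markers > 0)
        assert res.matching_residual < 0.05 * currents_norm_sq(
            template50.points, res.config.sigma_W)


def test_registration_config_validation():
    with pytest.raises(ValueError):
        RegistrationConfig(n_timesteps=3)
    with pytest.raises(ValueError):
        RegistrationConfig(sigma_V=-1.0)
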