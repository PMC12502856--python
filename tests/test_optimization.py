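import numpy as np
import pytest

import tensortomo as tt
from tensortomo.optimization import basis_map
from tensortomo.basis_sets import SegmentResponse

from conftest import random_geometry


def finite_difference_gradient(fun, x, eps=1e-6, n_probe=40, rng=None):
    """Central finite differences of ``fun`` at randomly probed entries."""
    rng = rng or np.random.default_rng(0)
    flat = x.ravel().copy()
    idx = rng.choice(flat.size, size=min(n_probe, flat.size), replace=False)
    grads = np.empty(len(idx))
    for n, i in enumerate(idx):
        plus, minus = flat.copy(), flat.copy()
        plus[i] += eps
        minus[i] -= eps
        grads[n] = (fun(plus.reshape(x.shape))[0]
                    - fun(minus.reshape(x.shape))[0]) / (2 * eps)
    return idx, grads


class TestHuber:
    def test_quadratic_branch(self):
        assert np.isclose(tt.huber_value(0.5, 1.0), 0.125)

    def test_linear_branch(self):
        assert np.isclose(tt.huber_value(2.0, 1.0), 1.5)

    def test_continuous_at_seam(self):
        for r in (1.0, -1.0):
            quad = 0.5 * r ** 2
            lin = 1.0 * abs(r) - 0.5
            assert np.isclose(quad, lin)
            assert np.isclose(tt.huber_value(r, 1.0), quad)

    def test_gradient_matches_finite_differences(self):
        r = np.linspace(-3, 3, 31)
        eps = 1e-7
        fd = (tt.huber_value(r + eps, 0.7) - tt.huber_value(r - eps, 0.7)) / (2 * eps)
        assert np.allclose(tt.huber_grad(r, 0.7), fd, atol=1e-6)


class TestRegularizers:
    def test_constant_field_unpenalized_by_smoothers(self):
        field = np.full((4, 4, 4, 2), 3.0)
        for kind in ("laplacian", "total_variation"):
            value, grad = tt.regularizer_value_grad(field, kind)
            assert value == 0.0
            assert np.allclose(grad, 0.0)

    def test_l1_of_unit_voxel(self):
        field = np.zeros((3, 3, 3, 1))
        field[1, 1, 1, 0] = 1.0
        value, grad = tt.regularizer_value_grad(field, "l1")
        assert value == 1.0
        assert grad[1, 1, 1, 0] == 1.0
        assert np.sum(np.abs(grad)) == 1.0

    @pytest.mark.parametrize("kind", ["laplacian", "total_variation", "l1",
                                      "l2", "huber_norm"])
    def test_gradients_match_finite_differences(self, rng, kind):
        field = rng.normal(size=(5, 5, 5, 2))
        if kind == "l1":
            field += 0.5 * np.sign(field)  # stay away from the kink at 0
        _, grad = tt.regularizer_value_grad(field, kind, delta=0.05)

        def fun(x):
            return tt.regularizer_value_grad(x, kind, delta=0.05)

        idx, fd = finite_difference_gradient(fun, field, rng=rng)
        ref = np.maximum(np.abs(fd), 1.0)
        assert np.max(np.abs(grad.ravel()[idx] - fd) / ref) < 1e-5

    def test_per_coefficient_weight_matrix(self, rng):
        field = rng.normal(size=(3, 3, 3, 2))
        D = rng.uniform(0.5, 2.0, field.shape)
        value, grad = tt.regularizer_value_grad(field, "l2", D=D)
        assert np.isclose(value, 0.5 * np.sum((D * field) ** 2))
        assert np.allclose(grad, D * D * field)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            tt.regularizer_value_grad(np.zeros((2, 2, 2, 1)), "ridge")


class TestResidualAndGradient:
    def _problem(self, rng, n_proj=3, shape=(4, 4, 4), n_seg=4, lmax=2):
        g = random_geometry(rng, volume_shape=shape, n_projections=n_proj,
                            projection_shape=shape[1:])
        seg = tt.DetectorSegments.evenly_spaced(n_seg, coverage="half")
        basis = tt.SphericalHarmonics(ell_max=lmax)
        response = tt.segment_integrals(basis, g, seg, mode="midpoint")
        return g, seg, basis, response

    def test_exact_solution_has_zero_loss_and_gradient(self, rng):
        g, seg, basis, response = self._problem(rng)
        # anisotropic perturbation on a strong isotropic background keeps the
        # simulated intensities physical (nonnegative)
        truth = 0.05 * rng.normal(size=g.volume_shape + (basis.n_coefficients,))
        truth[..., 0] += 3.0
        data = basis_map(tt.forward(truth, g), response)
        assert data.min() >= 0
        stack = tt.ProjectionStack(data=data)
        value, grad = tt.residual_and_gradient(truth, stack, response, g)
        assert value < 1e-16 * np.sum(data ** 2) + 1e-20
        assert np.max(np.abs(grad)) < 1e-8

    def test_zero_field_residual_is_weighted_data(self, rng):
        g, seg, basis, response = self._problem(rng)
        data = rng.uniform(0, 2, (3, 4, 4, 4))
        weights = rng.integers(0, 2, data.shape).astype(float)
        stack = tt.ProjectionStack(data=data, weights=weights)
        value, _ = tt.residual_and_gradient(
            np.zeros(g.volume_shape + (basis.n_coefficients,)), stack,
            response, g)
        assert np.isclose(value, 0.5 * np.sum((weights * data) ** 2))

    @pytest.mark.parametrize("loss", [
        tt.LossSpec(loss="squared"),
        tt.LossSpec(loss="huber", delta=0.1),
        tt.LossSpec(loss="squared", regularizers=[
            tt.RegularizerSpec("laplacian", 0.3),
            tt.RegularizerSpec("total_variation", 0.2, delta=0.05)]),
    ])
    def test_gradient_matches_finite_differences(self, rng, loss):
        g, seg, basis, response = self._problem(rng)
        data = rng.uniform(0, 2, (3, 4, 4, 4))
        stack = tt.ProjectionStack(data=data)
        field = rng.normal(size=g.volume_shape + (basis.n_coefficients,))
        _, grad = tt.residual_and_gradient(field, stack, response, g, loss)

        def fun(x):
            return tt.residual_and_gradient(x, stack, response, g, loss)

        idx, fd = finite_difference_gradient(fun, field, rng=rng)
        ref = np.maximum(np.abs(fd), 1.0)
        assert np.max(np.abs(grad.ravel()[idx] - fd) / ref) < 1e-5

    def test_masked_measurements_have_no_influence(self, rng):
        g, seg, basis, response = self._problem(rng)
        data = rng.uniform(0, 2, (3, 4, 4, 4))
        weights = np.ones_like(data)
        weights[1, 2, 2, :] = 0.0
        field = rng.normal(size=g.volume_shape + (basis.n_coefficients,))
        stack = tt.ProjectionStack(data=data, weights=weights)
        v1, g1 = tt.residual_and_gradient(field, stack, response, g)
        data2 = data.copy()
        data2[1, 2, 2, :] = 1e6  # perturb only the masked measurements
        stack2 = tt.ProjectionStack(data=data2, weights=weights)
        v2, g2 = tt.residual_and_gradient(field, stack2, response, g)
        assert v1 == v2
        assert np.array_equal(g1, g2)

    def test_nan_field_rejected(self, rng):
        g, seg, basis, response = self._problem(rng)
        stack = tt.ProjectionStack(data=np.ones((3, 4, 4, 4)))
        field = np.zeros(g.volume_shape + (basis.n_coefficients,))
        field[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            tt.residual_and_gradient(field, stack, response, g)


class TestGradientDescent:
    @staticmethod
    def _quadratic(H, b):
        # convex quadratic f = 0.5 ||Hx - b||^2
        def fun(x):
            r = H @ x - b
            return 0.5 * float(r @ r), H.T @ r
        return fun

    def test_single_plain_step(self):
        def fun(x):
            return float(x ** 2), 2 * x
        result = tt.gradient_descent(fun, np.array(1.0), step=0.4, max_iter=1)
        assert np.isclose(result.x, 0.2)

    def test_converges_to_exact_solution_of_quadratic(self, rng):
        H = rng.normal(size=(6, 6))
        H = H @ H.T / 6 + np.eye(6)
        b = rng.normal(size=6)
        fun = self._quadratic(H, b)
        exact = np.linalg.solve(H.T @ H, H.T @ b)
        result = tt.gradient_descent(fun, np.zeros(6),
                                     step=0.9 / np.linalg.norm(H.T @ H, 2),
                                     max_iter=5000, tol=0.0)
        assert np.max(np.abs(result.x - exact)) < 1e-6

    def test_nesterov_accelerates_ill_conditioned_quadratic(self):
        H = np.diag([1.0, 30.0])
        b = np.array([1.0, 1.0])
        fun = self._quadratic(H, b)
        step = 1.0 / 900  # 1 / L for condition number 900

        def iterations_to_target(nesterov):
            res = tt.gradient_descent(fun, np.zeros(2), step=step,
                                      nesterov=nesterov, max_iter=3000)
            trace = res.loss_trace
            below = np.nonzero(trace < 1e-6 * trace[0])[0]
            return below[0] if len(below) else len(trace)

        assert iterations_to_target(True) < iterations_to_target(False)

    def test_nan_loss_aborts_with_diagnostic(self):
        def fun(x):
            return float("nan"), x
        with pytest.raises(RuntimeError, match="non-finite"):
            tt.gradient_descent(fun, np.zeros(2), step=1.0, max_iter=5)


class TestLbfgs:
    def test_quadratic_bowl_recovered(self, rng):
        H = np.diag([1.0, 4.0, 9.0])
        b = np.array([1.0, -2.0, 0.5])

        def fun(x):
            r = H @ x - b
            return 0.5 * float(r @ r), H.T @ r

        exact = np.linalg.solve(H, b)
        result = tt.lbfgs_minimize(fun, np.zeros(3), max_iter=200,
                                   stopping=1e-15)
        assert np.max(np.abs(result.x - exact)) < 1e-8

    def test_rosenbrock_from_standard_start(self):
        def fun(xy):
            x, y = xy
            value = (1 - x) ** 2 + 100 * (y - x ** 2) ** 2
            grad = np.array([-2 * (1 - x) - 400 * x * (y - x ** 2),
                             200 * (y - x ** 2)])
            return float(value), grad

        result = tt.lbfgs_minimize(fun, np.array([-1.2, 1.0]), max_iter=500,
                                   stopping=1e-16)
        assert fun(result.x)[0] < 1e-6

    def test_deterministic_given_start(self, rng):
        def fun(x):
            return float(np.sum((x - 1) ** 4)), 4 * (x - 1) ** 3
        x0 = rng.normal(size=4)
        r1 = tt.lbfgs_minimize(fun, x0.copy(), max_iter=50)
        r2 = tt.lbfgs_minimize(fun, x0.copy(), max_iter=50)
        assert np.array_equal(r1.x, r2.x)
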