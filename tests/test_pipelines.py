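import numpy as np
import pytest

import tensortomo as tt
from tensortomo.basis_sets import SegmentResponse
from tensortomo.optimization import basis_map

from conftest import random_geometry
from _oracles import dense_system_matrix


@pytest.fixture(scope="module")
def scalar_phantom():
    spec = tt.PhantomSpec(texture="isotropic",
                          basis=tt.SphericalHarmonics(ell_max=0))
    field, axis, support = tt.make_phantom(spec)
    geometry = tt.acquisition_geometry(spec)
    segments = tt.DetectorSegments.evenly_spaced(spec.n_segments)
    stack = tt.simulate_experiment(field, geometry, segments, spec.basis)
    return spec, field, support, geometry, segments, stack


@pytest.fixture(scope="module")
def sh4_phantom():
    spec = tt.PhantomSpec()  # uniaxial fiber, SH ell_max 4, 16^3, S = 60
    field, axis, support = tt.make_phantom(spec)
    geometry = tt.acquisition_geometry(spec)
    segments = tt.DetectorSegments.evenly_spaced(spec.n_segments)
    stack = tt.simulate_experiment(field, geometry, segments, spec.basis)
    return spec, field, axis, support, geometry, segments, stack


class TestSirt:
    def test_matches_dense_linear_algebra_oracle(self, rng):
        g = random_geometry(rng, volume_shape=(6, 6, 6), n_projections=4,
                            projection_shape=(6, 6))
        seg = tt.DetectorSegments.evenly_spaced(4)
        basis = tt.SphericalHarmonics(ell_max=2)
        response = tt.segment_integrals(basis, g, seg, mode="midpoint")
        A = dense_system_matrix(g, response)
        N = basis.n_coefficients
        truth = 0.05 * rng.normal(size=(6, 6, 6, N))
        truth[..., 0] += 2.0
        b = A @ truth.reshape(-1)
        stack = tt.ProjectionStack(
            data=b.reshape(4, 6, 6, 4))
        rec = tt.run_sirt(stack, g, basis, seg, max_iter=8)
        # explicit SIRT on the dense matrix with |A|-based weights
        Aabs = np.abs(A)
        R = np.zeros(A.shape[0])
        rs = Aabs.sum(axis=1)
        R[rs > 0] = 1 / rs[rs > 0]
        C = np.zeros(A.shape[1])
        cs = Aabs.sum(axis=0)
        C[cs > 0] = 1 / cs[cs > 0]
        x = np.zeros(A.shape[1])
        for _ in range(8):
            x = x + C * (A.T @ (R * (b - A @ x)))
        assert np.max(np.abs(rec.coefficients.reshape(-1) - x)) < 1e-8

    def test_zero_data_is_fixed_point(self, rng):
        g = random_geometry(rng, volume_shape=(6, 6, 6), n_projections=3,
                            projection_shape=(6, 6))
        seg = tt.DetectorSegments.evenly_spaced(4)
        basis = tt.SphericalHarmonics(ell_max=0)
        stack = tt.ProjectionStack(data=np.zeros((3, 6, 6, 4)))
        rec = tt.run_sirt(stack, g, basis, seg, max_iter=5)
        assert np.array_equal(rec.coefficients, 0 * rec.coefficients)

    def test_recovers_noiseless_scalar_phantom(self, scalar_phantom):
        spec, field, support, g, seg, stack = scalar_phantom
        rec = tt.run_sirt(stack, g, spec.basis, seg, max_iter=20)
        r = np.corrcoef(rec.coefficients.ravel(), field.ravel())[0, 1]
        assert r >= 0.95

    def test_loss_trace_non_increasing_on_consistent_data(self, scalar_phantom):
        spec, field, support, g, seg, stack = scalar_phantom
        rec = tt.run_sirt(stack, g, spec.basis, seg, max_iter=15)
        trace = np.asarray(rec.provenance["loss_trace"])
        assert np.all(np.diff(trace) <= 1e-9 * trace[0])

    def test_input_stack_unmodified(self, scalar_phantom):
        spec, field, support, g, seg, stack = scalar_phantom
        before = stack.data.copy()
        tt.run_sirt(stack, g, spec.basis, seg, max_iter=3)
        assert np.array_equal(stack.data, before)


class TestMitra:
    def test_reduces_to_sirt_without_regularization(self, sh4_phantom):
        spec, field, axis, support, g, seg, stack = sh4_phantom
        rec_s = tt.run_sirt(stack, g, spec.basis, seg, max_iter=6)
        rec_m = tt.run_mitra(stack, g, spec.basis, seg, max_iter=6)
        assert np.max(np.abs(rec_s.coefficients - rec_m.coefficients)) < 1e-12

    def test_l1_weight_sweep_shrinks_solution_monotonically(self, scalar_phantom):
        spec, field, support, g, seg, stack = scalar_phantom
        norms = []
        with np.errstate(all="ignore"):
            for mu in (0.0, 1.0, 10.0, 100.0):
                rec = tt.run_mitra(
                    stack, g, spec.basis, seg, max_iter=10,
                    regularizers=[tt.RegularizerSpec("l1", mu)])
                norms.append(np.abs(rec.coefficients).sum())
        assert all(n2 <= n1 + 1e-9 for n1, n2 in zip(norms, norms[1:]))

    def test_momentum_recovery_of_sh_phantom(self, sh4_phantom):
        spec, field, axis, support, g, seg, stack = sh4_phantom
        rec = tt.run_mitra(stack, g, spec.basis, seg, nesterov=True,
                           max_iter=20)
        r = np.corrcoef(rec.coefficients[support].ravel(),
                        field[support].ravel())[0, 1]
        assert r >= 0.9

    def test_sh_l1_combination_warns_about_rotational_bias(self, scalar_phantom):
        spec, field, support, g, seg, stack = scalar_phantom
        with pytest.warns(UserWarning, match="rotational"):
            tt.run_mitra(stack, g, spec.basis, seg, max_iter=1,
                         regularizers=[tt.RegularizerSpec("l1", 0.1)])


class TestSigtt:
    def test_exact_fit_of_noiseless_phantom(self, sh4_phantom):
        spec, field, axis, support, g, seg, stack = sh4_phantom
        rec = tt.run_sigtt(stack, g, seg, ell_max=4, laplacian_weight=0.0,
                           max_iter=1500, stopping=1e-18)
        trace = rec.provenance["loss_trace"]
        assert trace[-1] < 1e-8 * trace[0]

    def test_strong_laplacian_flattens_field(self, scalar_phantom):
        spec, field, support, g, seg, stack = scalar_phantom
        rec = tt.run_sigtt(stack, g, seg, ell_max=0, laplacian_weight=1e8,
                           max_iter=200, stopping=1e-14)
        c = rec.coefficients[..., 0]
        assert np.std(c) < 0.05 * (np.abs(np.mean(c)) + 1e-12)

    def test_regularization_helps_on_noisy_data(self):
        spec = tt.PhantomSpec(volume_shape=(8, 8, 8), n_inner=10,
                              noise=("gaussian", 0.05), seed=11)
        field, axis, support = tt.make_phantom(spec)
        g = tt.acquisition_geometry(spec)
        seg = tt.DetectorSegments.evenly_spaced(spec.n_segments)
        stack = tt.simulate_experiment(field, g, seg, spec.basis,
                                       noise=spec.noise, seed=spec.seed)

        def err(mu):
            rec = tt.run_sigtt(stack, g, seg, ell_max=4, laplacian_weight=mu,
                               max_iter=150, stopping=1e-12)
            return np.sqrt(np.mean((rec.coefficients - field) ** 2))

        errors = {mu: err(mu) for mu in (0.0, 0.03, 0.1, 0.3)}
        assert min(errors[mu] for mu in (0.03, 0.1, 0.3)) <= errors[0.0]


class TestDiscreteDirections:
    def test_single_covering_direction_reduces_to_scalar_sirt(
            self, scalar_phantom):
        spec, field, support, g, seg, stack = scalar_phantom
        nn = tt.NearestNeighborBasis(grid=np.array([[0.0, 0.0, 1.0]]))
        rec_dd = tt.run_dd(stack, g, nn, seg, max_iter=10)
        rec_sirt = tt.run_sirt(stack, g, nn, seg, max_iter=10,
                               response_mode="adaptive")
        assert np.max(np.abs(rec_dd.coefficients - rec_sirt.coefficients)) < 1e-12

    def test_isotropic_phantom_collapses_channels(self, scalar_phantom):
        spec, field, support, g, seg, stack = scalar_phantom
        # 4 in-plane directions at the detector-segment centers, so every
        # direction is probed by some segments at every rotation
        seg_centers = tt.DetectorSegments.evenly_spaced(4).centers
        grid = np.column_stack([np.zeros(4), np.cos(seg_centers),
                                np.sin(seg_centers)])
        nn = tt.NearestNeighborBasis(grid=grid)
        rec_dd = tt.run_dd(stack, g, nn, seg, max_iter=15)
        scalar = tt.run_sirt(
            stack, g, tt.NearestNeighborBasis(grid=np.array([[0.0, 0, 1.0]])),
            seg, max_iter=15, response_mode="adaptive").coefficients[..., 0]
        for m in range(nn.n_coefficients):
            r = np.corrcoef(rec_dd.coefficients[..., m].ravel(),
                            scalar.ravel())[0, 1]
            assert r >= 0.9

    def test_channel_permutation_equivariance(self, scalar_phantom):
        spec, field, support, g, seg, stack = scalar_phantom
        centers = tt.DetectorSegments.evenly_spaced(3).centers
        grid = np.column_stack([np.zeros(3), np.cos(centers), np.sin(centers)])
        perm = np.array([2, 0, 1])
        rec1 = tt.run_dd(stack, g, tt.NearestNeighborBasis(grid=grid), seg,
                         max_iter=5)
        rec2 = tt.run_dd(stack, g, tt.NearestNeighborBasis(grid=grid[perm]),
                         seg, max_iter=5)
        assert np.allclose(rec1.coefficients[..., perm], rec2.coefficients,
                           atol=1e-12)


class TestCrossPipelineConsistency:
    def test_sigtt_and_mitra_fit_the_same_noiseless_data(self, sh4_phantom):
        spec, field, axis, support, g, seg, stack = sh4_phantom
        basis = spec.basis
        response = tt.segment_integrals(basis, g, seg, mode="midpoint")
        rms_data = np.sqrt(np.mean(stack.data ** 2))
        for rec in (
            tt.run_sigtt(stack, g, seg, ell_max=4, max_iter=300,
                         stopping=1e-14),
            tt.run_mitra(stack, g, basis, seg, nesterov=True, max_iter=200),
        ):
            model = basis_map(tt.forward(rec.coefficients, g), response)
            rel_rms = np.sqrt(np.mean((model - stack.data) ** 2)) / rms_data
            assert rel_rms <= 0.01
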