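"""Reconstruction pipelines: SIRT, MITRA, SIGTT and discrete directions (DD).

Each pipeline assembles the forward model (projector + detector response),
a loss, and an optimizer into a ready-to-run recipe:

* ``run_sirt`` — the simultaneous iterative reconstruction technique,
  formulated as preconditioned gradient descent on a weighted least-squares
  problem: ``x <- x + C A^T R (b - A x)`` with ``R``/``C`` the reciprocal
  row/column sums of the system matrix.  Semi-convergent, hence implicitly
  regularized by early stopping.
* ``run_mitra`` — modular iterative tomographic reconstruction: the same
  preconditioned update extended with arbitrary regularizers and optional
  Nesterov momentum.  With no regularizers and no momentum it reproduces
  SIRT exactly.
* ``run_sigtt`` — spherical integral geometric tensor tomography: a
  spherical-harmonic basis, squared loss, finite-difference Laplacian
  regularization, minimized with L-BFGS-B and a relative-loss-change stop.
* ``run_dd`` — discrete directions: splits the tensor problem into
  independent scalar SIRT reconstructions, one per orientation-grid
  direction of a nearest-neighbor basis.

All pipelines start from zero (the problems are convex), leave their input
stacks untouched and record a loss trace in the output provenance.
"""

from __future__ import annotations

import warnings

import numpy as np

from .geometry import Geometry, DetectorSegments
from .basis_sets import (BasisSet, SphericalHarmonics, NearestNeighborBasis,
                         SegmentResponse, segment_integrals)
from .data_io import ProjectionStack, ReconstructionOutput
from .projector import forward, adjoint, sirt_preconditioners
from .optimization import (LossSpec, RegularizerSpec, basis_map,
                           basis_map_adjoint, regularizer_value_grad,
                           lbfgs_minimize)

__all__ = ["run_sirt", "run_mitra", "run_sigtt", "run_dd"]


def _segment_response(basis: BasisSet, geometry: Geometry,
                      segments: DetectorSegments,
                      mode: str = "midpoint") -> SegmentResponse:
    return segment_integrals(basis, geometry, segments, mode=mode)


def _preconditioned_descent(stack: ProjectionStack, geometry: Geometry,
                            response: SegmentResponse, max_iter: int,
                            regularizers=(), nesterov: bool = False):
    """Shared SIRT/MITRA iteration.

    Minimizes the row-sum-weighted least squares ``0.5 sum R (w r)^2`` (plus
    optional regularizers) by preconditioned gradient descent with unit step,
    which for the bare least-squares problem is exactly the classic SIRT
    update ``x <- x + C A^T R (b - A x)``.
    """
    X, Y, Z = geometry.volume_shape
    N = response.B.shape[2]
    C_pre, R_pre = sirt_preconditioners(geometry, response)
    x = np.zeros((X, Y, Z, N))
    x_prev = x.copy()
    trace = []
    for t in range(max_iter):
        if nesterov and t > 0:
            y = x + t / (t + 3) * (x - x_prev)
        else:
            y = x
        model = basis_map(forward(y, geometry), response)
        r = stack.weights * (model - stack.data)
        value = 0.5 * np.sum(R_pre * r ** 2)
        grad = adjoint(basis_map_adjoint(R_pre * stack.weights * r, response),
                       geometry)
        for reg in regularizers:
            if reg.weight == 0:
                continue
            v, g = regularizer_value_grad(y, reg.kind, delta=reg.delta, D=reg.D)
            value += reg.weight * v
            grad += reg.weight * g
        trace.append(value)
        if len(trace) > 1 and value > 10 * trace[0]:
            raise RuntimeError(
                f"diverging iteration (loss grew from {trace[0]:.3e} to "
                f"{value:.3e}); check the data scaling or regularization")
        x_prev = x
        x = y - C_pre * grad
    return x, np.asarray(trace)


def run_sirt(stack: ProjectionStack, geometry: Geometry, basis: BasisSet,
             segments: DetectorSegments, max_iter: int = 20,
             response_mode: str = "midpoint") -> ReconstructionOutput:
    """SIRT reconstruction with row/column-sum preconditioners."""
    response = _segment_response(basis, geometry, segments, response_mode)
    x, trace = _preconditioned_descent(stack, geometry, response, max_iter)
    return ReconstructionOutput(
        coefficients=x, basis_descriptor=basis.descriptor(),
        provenance={"pipeline": "SIRT", "max_iter": max_iter,
                    "loss_trace": trace.tolist()})


def run_mitra(stack: ProjectionStack, geometry: Geometry, basis: BasisSet,
              segments: DetectorSegments, regularizers=(),
              nesterov: bool = False, max_iter: int = 20,
              response_mode: str = "midpoint") -> ReconstructionOutput:
    """MITRA: preconditioned descent with regularizers and optional momentum.

    With an empty regularizer list and momentum off this is iterate-for-
    iterate identical to :func:`run_sirt`.
    """
    regularizers = list(regularizers)
    if isinstance(basis, SphericalHarmonics):
        for reg in regularizers:
            if reg.kind in ("l1", "huber_norm"):
                warnings.warn(
                    "l1/huber_norm penalties on spherical-harmonic "
                    "coefficients are not rotational invariants and can bias "
                    "the solution towards certain directions", stacklevel=2)
    response = _segment_response(basis, geometry, segments, response_mode)
    x, trace = _preconditioned_descent(stack, geometry, response, max_iter,
                                       regularizers=regularizers,
                                       nesterov=nesterov)
    return ReconstructionOutput(
        coefficients=x, basis_descriptor=basis.descriptor(),
        provenance={"pipeline": "MITRA", "max_iter": max_iter,
                    "nesterov": nesterov,
                    "regularizers": [(r.kind, r.weight) for r in regularizers],
                    "loss_trace": trace.tolist()})


def run_sigtt(stack: ProjectionStack, geometry: Geometry,
              segments: DetectorSegments, ell_max: int = 4,
              laplacian_weight: float = 0.0, max_iter: int = 50,
              stopping: float = 1e-4,
              response_mode: str = "midpoint") -> ReconstructionOutput:
    """SIGTT: spherical harmonics + squared loss + Laplacian, via L-BFGS-B."""
    from .optimization import residual_and_gradient  # local to avoid cycle noise
    basis = SphericalHarmonics(ell_max=ell_max)
    response = _segment_response(basis, geometry, segments, response_mode)
    regs = []
    if laplacian_weight > 0:
        regs.append(RegularizerSpec("laplacian", laplacian_weight))
    loss = LossSpec(loss="squared", regularizers=regs)
    X, Y, Z = geometry.volume_shape
    x0 = np.zeros((X, Y, Z, basis.n_coefficients))

    def fun(x):
        return residual_and_gradient(x, stack, response, geometry, loss)

    result = lbfgs_minimize(fun, x0, max_iter=max_iter, stopping=stopping)
    return ReconstructionOutput(
        coefficients=result.x, basis_descriptor=basis.descriptor(),
        provenance={"pipeline": "SIGTT", "ell_max": ell_max,
                    "laplacian_weight": laplacian_weight,
                    "max_iter": max_iter, "stopping": stopping,
                    "converged": result.converged,
                    "loss_trace": result.loss_trace.tolist()})


def run_dd(stack: ProjectionStack, geometry: Geometry,
           basis: NearestNeighborBasis, segments: DetectorSegments,
           max_iter: int = 20) -> ReconstructionOutput:
    """Discrete directions: independent scalar SIRT per grid direction.

    For each orientation-grid direction ``m``, the measurements ``(s, c)``
    whose segment arc overlaps cell ``m`` (nearest-neighbor response
    ``B[s, c, m] > 0``) are reconstructed as a scalar tomogram, weighting
    each measurement by its arc fraction ``B[s, c, m]`` so partially
    assigned segments contribute proportionally.  Channels are independent;
    a direction probed by no measurement yields a zero channel and a
    warning.
    """
    response = segment_integrals(basis, geometry, segments, mode="adaptive")
    B = response.B  # (S, C, M) arc fractions in [0, 1]
    S, C, M = B.shape
    X, Y, Z = geometry.volume_shape
    coefficients = np.zeros((X, Y, Z, M))
    traces = []
    for m in range(M):
        Bm = B[:, :, m]
        if not np.any(Bm > 0):
            warnings.warn(f"orientation-grid direction {m} is probed by no "
                          "measurement; its channel is zeroed", stacklevel=2)
            traces.append([])
            continue
        sub_response = SegmentResponse(Bm[:, :, None])  # scalar basis (N=1)
        sub_weights = stack.weights * (Bm > 0)[:, None, None, :]
        sub_stack = ProjectionStack(data=stack.data, diode=stack.diode,
                                    weights=sub_weights)
        xm, trace = _preconditioned_descent(sub_stack, geometry, sub_response,
                                            max_iter)
        coefficients[..., m] = xm[..., 0]
        traces.append(trace.tolist())
    return ReconstructionOutput(
        coefficients=coefficients, basis_descriptor=basis.descriptor(),
        provenance={"pipeline": "DD", "max_iter": max_iter,
                    "loss_trace": traces})
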