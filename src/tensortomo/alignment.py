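"""Projection alignment by iterative cross-correlation (phase matching).

Parasitic sample-stage movement during goniometer rotation displaces each
projection by sub-pixel offsets in the scan plane.  The phase-matching
procedure estimates these offsets from a scalar sinogram — typically the
transmission (diode) images or the azimuthally averaged scattering — by
enforcing tomographic self-consistency:

1. pre-center every projection on its center of mass;
2. reconstruct a scalar tomogram with the current offsets (SIRT);
3. re-project the tomogram;
4. register each measured projection against its synthetic counterpart by
   cross-correlation with Fourier-upsampled sub-pixel refinement;
5. update the offsets with damping; repeat until the largest offset change
   falls below a tolerance.

The overall translation of the sample is not observable (a gauge freedom),
so the mean offset is constrained to zero along each axis.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .geometry import Geometry, rotation_matrix
from .basis_sets import SegmentResponse
from .pipelines import _preconditioned_descent
from .data_io import ProjectionStack
from .projector import forward

__all__ = ["AlignmentResult", "phase_matching_align",
           "sort_projections_by_direction"]


@dataclass
class AlignmentResult:
    """Recovered per-projection offsets and diagnostics."""

    j_offsets: np.ndarray
    k_offsets: np.ndarray
    convergence_trace: np.ndarray  # max offset change per iteration, px
    converged: bool
    reconstruction: np.ndarray     # final scalar tomogram (X, Y, Z)


def _center_of_mass_offsets(sinogram: np.ndarray):
    """Offsets that center each projection's mass on the grid center."""
    S, J, K = sinogram.shape
    jj = np.arange(J)
    kk = np.arange(K)
    total = sinogram.sum(axis=(1, 2))
    com_j = (sinogram.sum(axis=2) * jj).sum(axis=1) / total
    com_k = (sinogram.sum(axis=1) * kk).sum(axis=1) / total
    return (J - 1) / 2 - com_j, (K - 1) / 2 - com_k


def phase_matching_align(sinogram: np.ndarray, geometry: Geometry,
                         max_iter: int = 20, tol: float = 0.1,
                         damping: float = 0.8, recon_iter: int = 10,
                         upsample_factor: int = 10) -> AlignmentResult:
    """Estimate per-projection offsets from a scalar sinogram.

    ``sinogram`` has shape ``(S, J, K)``.  Returns offsets in scan-step
    units (sub-pixel), meant to overwrite the ``j_offsets`` / ``k_offsets``
    of the geometry (or the corresponding file fields).  ``tol`` is the
    largest per-iteration offset change (in pixels) at which the loop
    stops; non-convergence is reported through the result flag rather than
    an exception.
    """
    sinogram = np.asarray(sinogram, dtype=float)
    if sinogram.ndim != 3:
        raise ValueError("sinogram must have shape (S, J, K)")
    S, J, K = sinogram.shape
    if S != geometry.n_projections or (J, K) != geometry.projection_shape:
        raise ValueError("sinogram shape does not match the geometry")
    if S < 2:
        raise ValueError("alignment needs at least two projections")
    if not np.any(sinogram > 0):
        raise ValueError("sinogram is blank (all zeros)")

    geo = copy.deepcopy(geometry)
    dj, dk = _center_of_mass_offsets(sinogram)
    dj -= dj.mean()
    dk -= dk.mean()

    stack = ProjectionStack(data=sinogram[..., None])
    scalar_response = SegmentResponse(np.ones((S, 1, 1)))
    trace = []
    converged = False
    recon = None
    for _ in range(max_iter):
        geo.j_offsets = dj
        geo.k_offsets = dk
        recon, _ = _preconditioned_descent(stack, geo, scalar_response,
                                           recon_iter)
        synthetic = forward(recon, geo)[..., 0]
        shift_j = np.empty(S)
        shift_k = np.empty(S)
        for s in range(S):
            shift, _, _ = phase_cross_correlation(
                sinogram[s], synthetic[s], upsample_factor=upsample_factor,
                normalization=None)
            shift_j[s], shift_k[s] = shift
        # moving the synthetic image by +d requires changing the ray-origin
        # offset by -d
        new_dj = dj - damping * shift_j
        new_dk = dk - damping * shift_k
        new_dj -= new_dj.mean()
        new_dk -= new_dk.mean()
        change = max(np.max(np.abs(new_dj - dj)), np.max(np.abs(new_dk - dk)))
        trace.append(change)
        dj, dk = new_dj, new_dk
        if change < tol:
            converged = True
            break
    return AlignmentResult(j_offsets=dj, k_offsets=dk,
                           convergence_trace=np.asarray(trace),
                           converged=converged,
                           reconstruction=recon[..., 0])


def sort_projections_by_direction(geometry: Geometry) -> np.ndarray:
    """Greedy ordering of projections by beam-direction proximity.

    Starting from projection 0, repeatedly appends the unvisited projection
    whose sample-frame beam direction is closest (by angle) to the current
    one.  Useful for inspecting alignment results, where neighboring
    projection directions should have similar offsets.  Returns a
    permutation of ``range(S)``.
    """
    S = geometry.n_projections
    dirs = np.stack([rotation_matrix(geometry, s).T @ geometry.p_direction
                     for s in range(S)])
    order = [0]
    remaining = set(range(1, S))
    while remaining:
        current = dirs[order[-1]]
        rem = sorted(remaining)
        dots = np.clip(dirs[rem] @ current, -1.0, 1.0)
        nxt = rem[int(np.argmax(dots))]
        order.append(nxt)
        remaining.discard(nxt)
    return np.asarray(order)
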