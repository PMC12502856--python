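"""Per-voxel quantities derived from a reconstructed coefficient field.

From the voxel-wise reciprocal-space map ``W(q)`` these routines compute the
mean (isotropic) scattering intensity, the second-moment tensor

    T_ij = integral over the sphere of W(q) q_i q_j dOmega,

its eigensystem, the main nanostructure orientation and the fractional
anisotropy (FA).  The main orientation is the eigenvector of the largest
eigenvalue for structures scattering into two opposite polar caps, and of
the smallest eigenvalue for structures scattering into an equatorial band
(e.g. fiber symmetry).  FA is the scale-free eigenvalue-dispersion measure
of diffusion-tensor imaging: 0 for isotropic scattering, 1 when all
scattering is concentrated along a single axis.

The second moment is left unnormalized (no division by the spherical mean);
FA and the orientation are invariant to this choice, and a normalized
variant is available via ``normalize=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .basis_sets import BasisSet, SphericalHarmonics
from ._sphere import fibonacci_sphere, gauss_sphere_quadrature

__all__ = [
    "DerivedMaps",
    "mean_intensity",
    "second_moment",
    "eigensystem",
    "fractional_anisotropy",
    "main_orientation",
    "relative_anisotropy",
    "compute_derived_maps",
]


def _field2d(field: np.ndarray, basis: BasisSet):
    field = np.asarray(field, dtype=float)
    if field.shape[-1] != basis.n_coefficients:
        raise ValueError(
            f"field has {field.shape[-1]} channels, basis expects "
            f"{basis.n_coefficients}")
    return field.reshape(-1, field.shape[-1]), field.shape[:-1]


def _quadrature_for(basis: BasisSet, n_nodes: int):
    """Sphere quadrature suited to the basis: an exact Gauss product grid for
    band-limited spherical harmonics, a near-uniform Fibonacci mesh (equal
    weights) otherwise."""
    if isinstance(basis, SphericalHarmonics):
        n_polar = max(basis.ell_max + 2, 4)
        pts, w = gauss_sphere_quadrature(n_polar, 2 * n_polar + 2)
    else:
        pts = fibonacci_sphere(max(n_nodes, 500))
        w = np.full(len(pts), 4 * np.pi / len(pts))
    return pts, w


def mean_intensity(field: np.ndarray, basis: BasisSet,
                   n_nodes: int = 2000) -> np.ndarray:
    """Spherical mean ``(1 / 4 pi) * integral of W(q) dOmega`` per voxel.

    For spherical harmonics this is analytic — only the degree-0 coefficient
    contributes, ``mean = c00 / sqrt(4 pi)``.  Other bases are integrated on
    a near-uniform mesh of at least 500 nodes.
    """
    flat, shape = _field2d(field, basis)
    if isinstance(basis, SphericalHarmonics):
        return (flat[:, 0] / np.sqrt(4 * np.pi)).reshape(shape)
    pts, w = _quadrature_for(basis, n_nodes)
    values = basis.evaluate(pts)  # (n, N)
    return ((flat @ values.T) @ w / (4 * np.pi)).reshape(shape)


def second_moment(field: np.ndarray, basis: BasisSet, n_nodes: int = 2000,
                  normalize: bool = False) -> np.ndarray:
    """Second-moment tensor ``T_ij = integral W(q) q_i q_j dOmega`` per voxel.

    Returns an array of symmetric 3x3 matrices, shape ``field.shape[:-1] +
    (3, 3)``.  Because ``q_i q_j`` is a degree-2 polynomial, only the degree
    0 and 2 components of ``W`` contribute; with a spherical-harmonic basis
    the Gauss-grid evaluation is therefore exact (a closed form in the
    coefficients).  With ``normalize=True`` the tensor is divided by the
    spherical integral of ``W``.
    """
    flat, shape = _field2d(field, basis)
    pts, w = _quadrature_for(basis, n_nodes)
    values = basis.evaluate(pts)                       # (n, N)
    outer = pts[:, :, None] * pts[:, None, :]          # (n, 3, 3)
    # M[i, a, b] = integral f_i(q) q_a q_b dOmega
    M = np.einsum("n,ni,nab->iab", w, values, outer)
    T = np.einsum("vi,iab->vab", flat, M)
    if normalize:
        total = flat @ (values.T @ w)  # integral of W over the sphere
        safe = np.where(np.abs(total) > 0, total, 1.0)
        T = T / safe[:, None, None]
    T = 0.5 * (T + np.swapaxes(T, -1, -2))  # enforce exact symmetry
    return T.reshape(shape + (3, 3))


def eigensystem(tensors: np.ndarray):
    """Eigenvalues (descending) and matching orthonormal eigenvectors.

    ``tensors`` has shape ``(..., 3, 3)``; returns ``(eigenvalues (..., 3),
    eigenvectors (..., 3, 3))`` with eigenvector ``[..., :, i]`` belonging
    to eigenvalue ``[..., i]``.
    """
    tensors = np.asarray(tensors, dtype=float)
    vals, vecs = np.linalg.eigh(tensors)   # ascending
    return vals[..., ::-1], vecs[..., ::-1]


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from the three second-moment eigenvalues.

        FA = sqrt(3/2) * sqrt(sum_i (l_i - mean)^2) / sqrt(sum_i l_i^2)

    0 for isotropic scattering (all eigenvalues equal), 1 when the
    scattering is concentrated along one direction and vanishes in the
    orthogonal ones.  All-zero eigenvalue triples are undefined and return
    NaN.  For positive-semidefinite inputs the result is clipped to [0, 1]
    to absorb round-off.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("expected a trailing axis of 3 eigenvalues")
    # FA is scale-free: normalize by the largest magnitude so that squaring
    # cannot under- or overflow for extreme eigenvalue scales
    peak = np.max(np.abs(lam), axis=-1, keepdims=True)
    lam = np.divide(lam, peak, out=np.zeros_like(lam), where=peak > 0)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam ** 2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    # snap the analytic endpoints when within round-off: dispersion below
    # machine noise is exactly isotropic, and the uniaxial maximum is 1
    fa = np.where(num <= 1e-13 * den, 0.0, fa)
    fa = np.where(np.abs(fa - 1.0) <= 1e-13, 1.0, fa)
    fa = np.where(den > 0, fa, np.nan)
    psd = np.all(lam >= -1e-12 * np.maximum(den[..., None], 1e-300), axis=-1)
    return np.where(psd, np.clip(fa, 0.0, 1.0), fa)


def main_orientation(second_moment: np.ndarray, mode: str = "polar_peaks",
                     return_degenerate: bool = False):
    """Main nanostructure orientation from the second-moment tensor.

    ``mode='polar_peaks'`` picks the eigenvector of the largest eigenvalue
    (scattering concentrated at two opposite poles); ``mode='equatorial_band'``
    picks the eigenvector of the smallest eigenvalue (scattering in a ring,
    e.g. fiber symmetry, where the fiber axis is normal to the ring).  The
    sign is fixed so the first component of largest magnitude is positive.

    A voxel whose relevant eigenvalue is separated from its neighbor by less
    than ``1e-9`` times the trace is orientationally ambiguous; the returned
    vector is still deterministic (eigendecomposition order) and, with
    ``return_degenerate=True``, a boolean mask flags such voxels.
    """
    if mode not in ("polar_peaks", "equatorial_band"):
        raise ValueError(f"unknown mode {mode!r}")
    T = np.asarray(second_moment, dtype=float)
    if not np.allclose(T, np.swapaxes(T, -1, -2), atol=1e-10):
        raise ValueError("second-moment tensor must be symmetric")
    vals, vecs = eigensystem(T)
    idx = 0 if mode == "polar_peaks" else 2
    nbr = 1
    v = vecs[..., :, idx]
    gap = np.abs(vals[..., idx] - vals[..., nbr])
    trace = np.abs(vals.sum(axis=-1))
    degenerate = gap < 1e-9 * np.maximum(trace, 1e-300)
    # sign convention: make the largest-magnitude leading component positive
    lead = np.take_along_axis(
        v, np.argmax(np.abs(v), axis=-1)[..., None], axis=-1)[..., 0]
    sign = np.where(lead < 0, -1.0, 1.0)
    v = v * sign[..., None]
    if return_degenerate:
        return v, degenerate
    return v


def relative_anisotropy(field: np.ndarray, basis: BasisSet,
                        n_nodes: int = 2000) -> np.ndarray:
    """Spherical standard deviation of ``W`` normalized by its mean.

    A simple basis-agnostic anisotropy measure computed on a near-uniform
    sphere mesh; NaN where the mean vanishes.
    """
    flat, shape = _field2d(field, basis)
    pts = fibonacci_sphere(max(n_nodes, 500))
    values = basis.evaluate(pts)
    W = flat @ values.T
    mean = W.mean(axis=-1)
    std = W.std(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ra = std / mean
    return np.where(mean != 0, ra, np.nan).reshape(shape)


@dataclass
class DerivedMaps:
    """Container for the standard per-voxel derived quantities."""

    mean_intensity: np.ndarray
    second_moment: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    fractional_anisotropy: np.ndarray
    main_orientation: np.ndarray
    orientation_mode: str = "polar_peaks"


def compute_derived_maps(field: np.ndarray, basis: BasisSet,
                         orientation_mode: str = "polar_peaks",
                         n_nodes: int = 2000) -> DerivedMaps:
    """All standard derived maps of a coefficient field in one pass."""
    T = second_moment(field, basis, n_nodes=n_nodes)
    vals, vecs = eigensystem(T)
    return DerivedMaps(
        mean_intensity=mean_intensity(field, basis, n_nodes=n_nodes),
        second_moment=T,
        eigenvalues=vals,
        eigenvectors=vecs,
        fractional_anisotropy=fractional_anisotropy(vals),
        main_orientation=main_orientation(T, mode=orientation_mode),
        orientation_mode=orientation_mode,
    )
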