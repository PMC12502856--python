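"""Spherical basis sets for the reciprocal-space map and their detector response.

A reconstruction expands the direction-dependent scattering function
``W(q)`` of each voxel in a finite set of functions on the unit sphere,

    W(q) = sum_i c_i f_i(q),

and the azimuthal detector segments probe averages of ``W`` along arcs on
the sphere.  Three linear basis families are provided:

* real spherical harmonics (``SphericalHarmonics``), band-limited at
  ``ell_max``, by default restricted to even degrees because scattered
  intensity obeys Friedel symmetry ``W(q) = W(-q)``;
* nearest-neighbor indicators on an orientation grid
  (``NearestNeighborBasis``), which split the sphere into cells and underpin
  discrete-directions reconstructions;
* spherical Gaussian kernels centered on an orientation grid
  (``GaussianKernelBasis``), a smooth alternative with a width parameter.

The detector response ``B[s, c, i]`` — how much basis function ``i``
contributes to segment ``c`` at sample rotation ``s`` — is the average of
``f_i`` along the probed arc, evaluated either by adaptive Newton–Cotes
(Simpson) quadrature or at the central angle of the segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.special import sph_harm_y

from .geometry import Geometry, DetectorSegments, probed_direction, rotation_matrix
from ._sphere import fibonacci_hemisphere

__all__ = [
    "BasisSet",
    "SphericalHarmonics",
    "NearestNeighborBasis",
    "GaussianKernelBasis",
    "SegmentResponse",
    "evaluate_basis",
    "segment_integrals",
    "rsm_on_grid",
    "basis_from_descriptor",
]

_DIR_TOL = 1e-9


def _check_directions(directions: np.ndarray) -> np.ndarray:
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if directions.shape[-1] != 3:
        raise ValueError("directions must have shape (..., 3)")
    norms = np.linalg.norm(directions, axis=-1)
    if np.any(np.abs(norms - 1) > 1e-6):
        raise ValueError("directions must be unit vectors")
    return directions


class BasisSet:
    """Common interface of the linear spherical basis sets."""

    friedel: bool = True

    @property
    def n_coefficients(self) -> int:
        raise NotImplementedError

    def evaluate(self, directions: np.ndarray) -> np.ndarray:
        """Basis-function values, shape ``(n_directions, N)``."""
        raise NotImplementedError

    def descriptor(self) -> dict:
        """Serializable description (kind + parameters) of this basis."""
        raise NotImplementedError


@dataclass
class SphericalHarmonics(BasisSet):
    """Real orthonormal spherical harmonics up to band limit ``ell_max``.

    Coefficients are ordered by ascending degree ``ell`` and, within each
    degree, by order ``m`` from ``-ell`` to ``+ell``.  By default only even
    degrees are included (Friedel-symmetric intensity, sufficient for
    half-circle SAXS detector coverage); set ``even_only=False`` for full
    360-degree WAXS data where odd degrees may carry signal.
    """

    ell_max: int = 0
    even_only: bool = True

    def __post_init__(self):
        if self.ell_max < 0:
            raise ValueError("ell_max must be nonnegative")
        step = 2 if self.even_only else 1
        self._orders = [(l, m) for l in range(0, self.ell_max + 1, step)
                        for m in range(-l, l + 1)]

    @property
    def friedel(self) -> bool:
        return self.even_only

    @property
    def orders(self) -> list[tuple[int, int]]:
        return list(self._orders)

    @property
    def n_coefficients(self) -> int:
        return len(self._orders)

    def evaluate(self, directions: np.ndarray) -> np.ndarray:
        d = _check_directions(directions)
        theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
        phi = np.arctan2(d[:, 1], d[:, 0])
        out = np.empty((len(d), self.n_coefficients))
        for i, (l, m) in enumerate(self._orders):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m == 0:
                out[:, i] = y.real
            elif m > 0:
                out[:, i] = np.sqrt(2) * (-1) ** m * y.real
            else:
                out[:, i] = np.sqrt(2) * (-1) ** m * y.imag
        return out

    def descriptor(self) -> dict:
        return {"kind": "spherical_harmonics", "ell_max": self.ell_max,
                "even_only": self.even_only}


def _geodesic_to_grid(directions: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Angles (radians) from each direction to the nearer of +/- each grid
    vector: shape ``(n_directions, M)``."""
    dots = np.abs(directions @ grid.T)
    return np.arccos(np.clip(dots, -1.0, 1.0))


@dataclass
class NearestNeighborBasis(BasisSet):
    """Indicator functions of the nearest orientation-grid direction.

    The sphere is partitioned into cells by geodesic distance to the grid
    (antipodally symmetrized, so a direction and its negative share a cell);
    basis function ``m`` is 1 inside cell ``m`` and 0 elsewhere.  The default
    grid is a hemispherical Fibonacci lattice; any grid of unit vectors can
    be supplied, e.g. :func:`tensortomo._sphere.truncated_icosahedron_faces`.
    """

    grid: np.ndarray = field(default_factory=lambda: fibonacci_hemisphere(16))

    def __post_init__(self):
        self.grid = _check_directions(self.grid)

    @property
    def n_coefficients(self) -> int:
        return len(self.grid)

    def evaluate(self, directions: np.ndarray) -> np.ndarray:
        d = _check_directions(directions)
        ang = _geodesic_to_grid(d, self.grid)
        nearest = np.argmin(ang, axis=1)  # ties: lowest grid index
        out = np.zeros((len(d), self.n_coefficients))
        out[np.arange(len(d)), nearest] = 1.0
        return out

    def descriptor(self) -> dict:
        return {"kind": "nearest_neighbor", "grid": np.asarray(self.grid)}


@dataclass
class GaussianKernelBasis(BasisSet):
    """Spherical Gaussian kernels centered on an orientation grid.

    Kernel ``m`` evaluates to ``exp(-d^2 / (2 sigma^2))`` where ``d`` is the
    geodesic angle to the nearer of the antipodal pair ``+/- grid[m]``;
    ``sigma`` is the kernel width in radians.  Kernels peak at 1 and are not
    normalized to unit integral — the normalization is absorbed into the
    coefficients.
    """

    grid: np.ndarray = field(default_factory=lambda: fibonacci_hemisphere(16))
    sigma: float = 0.3

    def __post_init__(self):
        self.grid = _check_directions(self.grid)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def n_coefficients(self) -> int:
        return len(self.grid)

    def evaluate(self, directions: np.ndarray) -> np.ndarray:
        d = _check_directions(directions)
        ang = _geodesic_to_grid(d, self.grid)
        return np.exp(-(ang ** 2) / (2 * self.sigma ** 2))

    def descriptor(self) -> dict:
        return {"kind": "gaussian_kernel", "grid": np.asarray(self.grid),
                "sigma": self.sigma}


def basis_from_descriptor(desc: dict) -> BasisSet:
    """Rebuild a basis set from its serialized descriptor."""
    kind = desc["kind"]
    if kind == "spherical_harmonics":
        return SphericalHarmonics(ell_max=int(desc["ell_max"]),
                                  even_only=bool(desc.get("even_only", True)))
    if kind == "nearest_neighbor":
        return NearestNeighborBasis(grid=np.asarray(desc["grid"]))
    if kind == "gaussian_kernel":
        return GaussianKernelBasis(grid=np.asarray(desc["grid"]),
                                   sigma=float(desc["sigma"]))
    raise ValueError(f"unknown basis kind {kind!r}")


def evaluate_basis(basis: BasisSet, directions: np.ndarray) -> np.ndarray:
    """Evaluate all basis functions at the given unit directions."""
    return basis.evaluate(directions)


@dataclass
class SegmentResponse:
    """Detector-segment response matrix ``B`` of shape ``(S, C, N)``."""

    B: np.ndarray

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        if self.B.ndim != 3:
            raise ValueError("B must have shape (S, C, N)")
        if not np.all(np.isfinite(self.B)):
            raise ValueError("segment response contains non-finite entries")


def _adaptive_simpson(f, a: float, b: float, tol: float, max_depth: int = 48,
                      min_width: float = 1e-9):
    """Adaptive Simpson quadrature of a vector-valued function on [a, b].

    Returns the integral (not the average).  Subintervals narrower than
    ``min_width`` are accepted as-is — this bounds the work at jump
    discontinuities (nearest-neighbor indicator bases), where the local
    error estimate cannot shrink but the interval's contribution is already
    negligible.  Raises if the recursion depth is exhausted on a wide
    interval.
    """
    fa, fm, fb = f(a), f(0.5 * (a + b)), f(b)
    whole = (b - a) / 6 * (fa + 4 * fm + fb)

    def recurse(a, b, fa, fm, fb, whole, tol, depth):
        m = 0.5 * (a + b)
        lm, rm = 0.5 * (a + m), 0.5 * (m + b)
        flm, frm = f(lm), f(rm)
        left = (m - a) / 6 * (fa + 4 * flm + fm)
        right = (b - m) / 6 * (fm + 4 * frm + fb)
        err = np.max(np.abs(left + right - whole))
        if err < 15 * tol or (b - a) < min_width:
            return left + right + (left + right - whole) / 15
        if depth >= max_depth:
            raise RuntimeError("adaptive quadrature did not converge")
        return (recurse(a, m, fa, flm, fm, left, tol / 2, depth + 1)
                + recurse(m, b, fm, frm, fb, right, tol / 2, depth + 1))

    return recurse(a, b, fa, fm, fb, whole, tol, 0)


def _nn_arc_fractions(basis: "NearestNeighborBasis", dirs, a: float, b: float,
                      n_scan: int = 512) -> np.ndarray:
    """Exact arc-fraction response of a nearest-neighbor basis on [a, b].

    The cell assignment along the arc is piecewise constant, so the average
    of each indicator is the fraction of arc length its cell occupies.
    Change points are located on a uniform scan and refined by bisection to
    machine precision; flickers narrower than the scan resolution
    (tangential cell crossings) are below the response tolerance anyway.
    """
    grid = basis.grid
    phis = np.linspace(a, b, n_scan)
    idx = np.argmin(_geodesic_to_grid(dirs(phis), grid), axis=1)
    lengths = np.zeros(len(grid))
    run_start = a
    for k in np.nonzero(np.diff(idx))[0]:
        lo, hi = phis[k], phis[k + 1]
        left_cell = idx[k]
        for _ in range(48):  # bisect the boundary
            mid = 0.5 * (lo + hi)
            if np.argmin(_geodesic_to_grid(dirs(np.array([mid])), grid)) == left_cell:
                lo = mid
            else:
                hi = mid
        boundary = 0.5 * (lo + hi)
        lengths[left_cell] += boundary - run_start
        run_start = boundary
    lengths[idx[-1]] += b - run_start
    return lengths / (b - a)


def segment_integrals(basis: BasisSet, geometry: Geometry,
                      segments: DetectorSegments, mode: str = "adaptive",
                      tol: float = 1e-6) -> SegmentResponse:
    """Average of each basis function over each detector segment arc.

    ``B[s, c, i]`` is the mean of basis function ``i`` over the sample-frame
    directions probed by segment ``c`` at rotation ``s``.  ``mode='adaptive'``
    integrates smooth bases by adaptive Simpson quadrature to absolute
    tolerance ``tol``, and the piecewise-constant nearest-neighbor basis by
    exact arc fractions with bisected cell boundaries;
    ``mode='midpoint'`` evaluates at the central angle of each segment (the
    fast approximation).
    """
    if mode not in ("adaptive", "midpoint"):
        raise ValueError(f"unknown mode {mode!r}")
    S = geometry.n_projections
    C = segments.n_segments
    N = basis.n_coefficients
    B = np.empty((S, C, N))
    bounds = segments.boundaries
    theta = 0.5 * segments.two_theta
    q0 = geometry.detector_direction_origin
    q90 = geometry.detector_direction_positive_90
    p = geometry.p_direction
    for s in range(S):
        R = rotation_matrix(geometry, s)

        def dirs(phi):
            q_lab = (np.cos(theta) * (np.cos(phi)[:, None] * q0
                                      + np.sin(phi)[:, None] * q90)
                     - np.sin(theta) * p)
            return q_lab @ R  # sample-frame directions R^T q_lab

        if mode == "midpoint":
            B[s] = basis.evaluate(dirs(segments.centers))
            continue
        for c in range(C):
            a, b = bounds[c], bounds[c + 1]
            if isinstance(basis, NearestNeighborBasis):
                B[s, c] = _nn_arc_fractions(basis, dirs, a, b)
                continue

            def f(phi):
                return basis.evaluate(dirs(np.array([phi])))[0]

            try:
                integral = _adaptive_simpson(f, a, b, tol * (b - a))
            except RuntimeError as exc:
                raise RuntimeError(
                    f"segment integral did not converge (projection {s}, "
                    f"segment {c})") from exc
            B[s, c] = integral / (b - a)
    return SegmentResponse(B)


def rsm_on_grid(coefficients: np.ndarray, basis: BasisSet,
                sphere_mesh: np.ndarray) -> np.ndarray:
    """Evaluate ``W(q) = sum_i c_i f_i(q)`` on a mesh of unit vectors.

    ``coefficients`` may be a single length-``N`` vector or an array with a
    trailing coefficient axis (e.g. a voxel map); the result replaces that
    axis by the mesh axis.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape[-1] != basis.n_coefficients:
        raise ValueError(
            f"expected {basis.n_coefficients} coefficients, "
            f"got {coefficients.shape[-1]}")
    values = basis.evaluate(sphere_mesh)  # (n_mesh, N)
    return coefficients @ values.T
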