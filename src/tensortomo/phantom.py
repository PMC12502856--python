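"""Synthetic tensor-tomography experiments with known ground truth.

The generator produces voxel maps of reciprocal-space-map coefficients with
a known orientation field, forward-projects them through the same model the
reconstructions invert, and adds configurable noise and per-projection
misalignment — so every stage of the package (projection, reconstruction,
alignment, derived quantities) can be validated end to end without any
experimental data.

Two scattering archetypes are modeled on top of an isotropic background:
polar caps (strong scattering along an axis, two opposite poles) and an
equatorial band (strong scattering in the ring perpendicular to a fiber
axis, the typical fiber-symmetry SAXS signature).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .geometry import Geometry, DetectorSegments
from .basis_sets import (BasisSet, SphericalHarmonics, segment_integrals)
from .data_io import ProjectionStack
from .projector import forward
from .optimization import basis_map
from ._sphere import fibonacci_sphere, gauss_sphere_quadrature

__all__ = ["PhantomSpec", "make_phantom", "acquisition_geometry",
           "simulate_experiment"]

_TEXTURES = ("isotropic", "uniaxial_fiber", "concentric_shells")


@dataclass
class PhantomSpec:
    """Recipe for a synthetic experiment.

    ``anisotropy`` interpolates between an isotropic reciprocal-space map
    (0) and the pure polar-cap / equatorial-band shape (1).  ``noise`` is
    ``None``, ``('gaussian', sigma_rel)`` with the standard deviation given
    relative to the mean model intensity, or ``('poisson', scale)`` where
    ``scale`` converts intensities to expected counts.  ``shift_range``
    bounds the uniformly drawn per-projection misalignment in scan-step
    units.  The acquisition crosses ``n_inner`` uniformly spaced rotations
    with the listed tilt angles, mimicking a rotation + tilt goniometer.
    """

    volume_shape: tuple = (16, 16, 16)
    texture: str = "uniaxial_fiber"
    basis: BasisSet = dataclass_field(
        default_factory=lambda: SphericalHarmonics(ell_max=4))
    anisotropy: float = 0.7
    noise: tuple | None = None
    shift_range: float = 0.0
    n_inner: int = 20
    outer_tilts: tuple = (0.0, np.deg2rad(20.0), np.deg2rad(40.0))
    n_segments: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.texture not in _TEXTURES:
            raise ValueError(f"unknown texture {self.texture!r}")
        if not 0.0 <= self.anisotropy <= 1.0:
            raise ValueError("anisotropy must lie in [0, 1]")
        if any(n < 1 for n in self.volume_shape):
            raise ValueError("volume_shape must be positive")


def _support_and_orientation(spec: PhantomSpec):
    """Support mask, density and smoothly varying orientation field."""
    X, Y, Z = spec.volume_shape
    x, y, z = np.meshgrid(
        np.arange(X) - (X - 1) / 2, np.arange(Y) - (Y - 1) / 2,
        np.arange(Z) - (Z - 1) / 2, indexing="ij")
    r = np.sqrt(x ** 2 + y ** 2 + z ** 2)
    r_out = 0.42 * min(spec.volume_shape)
    if spec.texture == "concentric_shells":
        r_in = 0.5 * r_out
        support = (r <= r_out) & (r >= r_in)
        with np.errstate(invalid="ignore", divide="ignore"):
            axis = np.stack([x, y, z], axis=-1) / np.maximum(r, 1e-12)[..., None]
    else:
        support = r <= r_out
        # fiber axis: mostly z with a smooth position-dependent wobble
        axis = np.stack([
            0.25 * np.sin(2 * np.pi * y / max(Y, 1)),
            0.25 * np.cos(2 * np.pi * x / max(X, 1)),
            np.ones_like(z)], axis=-1)
        axis = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
    axis = np.where(support[..., None], axis, 0.0)
    density = support.astype(float)
    return support, density, axis


def _rsm_values(spec: PhantomSpec, density, axis, directions):
    """``W(q)`` per voxel on the given unit directions, shape (V, n_dir)."""
    A = spec.anisotropy
    if spec.texture == "isotropic" or A == 0:
        return density[:, None] * np.ones((1, len(directions)))
    dots2 = (axis @ directions.T) ** 2
    if spec.texture == "uniaxial_fiber":   # equatorial band, mean 1
        shape = 1.5 * (1.0 - dots2)
    else:                                   # polar caps, mean 1
        shape = 3.0 * dots2
    return density[:, None] * ((1 - A) + A * shape)


def make_phantom(spec: PhantomSpec):
    """Build the ground-truth coefficient field.

    Returns ``(field, orientations, support)`` where ``field`` has shape
    ``volume_shape + (N,)`` in the spec's basis, ``orientations`` holds the
    per-voxel symmetry axis (zero outside the support) and ``support`` is
    the boolean voxel mask.  The per-voxel map is
    ``density * [(1 - A) + A * shape(q . u)]`` with unit spherical mean, so
    ``anisotropy = 0`` yields perfectly isotropic voxels.  Deterministic —
    the spec's seed only drives the noise and shifts of
    :func:`simulate_experiment`.
    """
    basis = spec.basis
    if (spec.texture != "isotropic" and spec.anisotropy > 0
            and isinstance(basis, SphericalHarmonics) and basis.ell_max < 2):
        raise ValueError(
            "an anisotropic texture needs spherical harmonics of degree >= 2")
    support, density, axis = _support_and_orientation(spec)
    shape = spec.volume_shape
    flat_density = density.reshape(-1)
    flat_axis = axis.reshape(-1, 3)
    inside = flat_density > 0

    if isinstance(basis, SphericalHarmonics):
        pts, w = gauss_sphere_quadrature(max(basis.ell_max + 2, 4),
                                         2 * basis.ell_max + 6)
        values = basis.evaluate(pts)                       # (n, N)
        proj = values * w[:, None]                          # c_i = sum w W Y_i
    else:
        pts = fibonacci_sphere(1000)
        values = basis.evaluate(pts)
        proj = np.linalg.pinv(values).T                     # least-squares fit
    W = _rsm_values(spec, flat_density[inside], flat_axis[inside], pts)
    coeffs = np.zeros((len(flat_density), basis.n_coefficients))
    coeffs[inside] = W @ proj
    return coeffs.reshape(shape + (basis.n_coefficients,)), axis, support


def acquisition_geometry(spec: PhantomSpec) -> Geometry:
    """Rotation + tilt acquisition geometry matching the phantom spec.

    Inner angles are ``n_inner`` uniform steps over a full turn, crossed
    with the spec's outer tilts; the raster scan matches the voxel grid
    (scan step = voxel size = 1).
    """
    alphas = np.linspace(0.0, 2 * np.pi, spec.n_inner, endpoint=False)
    inner, outer = [], []
    for beta in spec.outer_tilts:
        inner.extend(alphas)
        outer.extend([beta] * len(alphas))
    X, Y, Z = spec.volume_shape
    return Geometry(inner_angles=np.array(inner), outer_angles=np.array(outer),
                    volume_shape=spec.volume_shape, projection_shape=(Y, Z))


def simulate_experiment(field: np.ndarray, geometry: Geometry,
                        segments: DetectorSegments, basis: BasisSet,
                        noise: tuple | None = None,
                        shifts: tuple | None = None,
                        seed: int = 0,
                        response_mode: str = "midpoint") -> ProjectionStack:
    """Forward-simulate a measured projection stack from a coefficient field.

    ``shifts`` is an optional ``(j_shifts, k_shifts)`` pair of per-
    projection misalignments applied as ray-origin offsets (the geometry
    passed in is not modified).  ``noise`` follows
    :class:`PhantomSpec`; negative intensities produced by Gaussian noise
    are clipped to zero with a warning.  The transmission images follow a
    Beer-Lambert law with the phantom's isotropic intensity as density
    proxy, giving the alignment signal realistic contrast.  All randomness
    is driven by ``seed``.
    """
    from .quantities import mean_intensity  # deferred: quantities imports basis_sets
    geo = copy.deepcopy(geometry)
    if shifts is not None:
        j_shifts, k_shifts = shifts
        geo.j_offsets = geo.j_offsets + np.asarray(j_shifts, dtype=float)
        geo.k_offsets = geo.k_offsets + np.asarray(k_shifts, dtype=float)
    response = segment_integrals(basis, geo, segments, mode=response_mode)
    data = basis_map(forward(field, geo), response)

    rng = np.random.default_rng(seed)
    if noise is not None:
        kind = noise[0]
        if kind == "gaussian":
            sigma = float(noise[1]) * data.mean()
            data = data + rng.normal(0.0, sigma, size=data.shape)
        elif kind == "poisson":
            scale = float(noise[1])
            data = rng.poisson(np.maximum(data, 0.0) * scale) / scale
        else:
            raise ValueError(f"unknown noise model {kind!r}")
    n_negative = int(np.sum(data < 0))
    if n_negative:
        warnings.warn(f"clipped {n_negative} negative intensities to zero",
                      stacklevel=2)
        data = np.clip(data, 0.0, None)

    density = mean_intensity(field, basis)
    line = forward(np.clip(density, 0.0, None)[..., None], geo)[..., 0]
    mu = 1.2 / max(line.max(), 1e-300)
    diode = np.exp(-mu * line)
    return ProjectionStack(data=data, diode=diode,
                           weights=np.ones_like(data))
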