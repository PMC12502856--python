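"""Meshes and quadrature rules on the unit sphere.

Used by the basis sets (orientation grids, segment integrals) and by the
derived-quantity calculations (spherical means and moments).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "fibonacci_sphere",
    "fibonacci_hemisphere",
    "gauss_sphere_quadrature",
    "truncated_icosahedron_faces",
]

_GOLDEN = (1 + np.sqrt(5)) / 2


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform points on the full unit sphere (Fibonacci lattice)."""
    if n < 1:
        raise ValueError("n must be positive")
    i = np.arange(n)
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    phi = 2 * np.pi * i / _GOLDEN
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """``n`` near-uniform points on the upper hemisphere (z >= 0).

    Suitable as an orientation grid for antipodally symmetric (Friedel)
    models, where a direction and its negative are equivalent.
    """
    if n < 1:
        raise ValueError("n must be positive")
    i = np.arange(n)
    z = 1 - (i + 0.5) / n  # z in (0, 1]
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    phi = 2 * np.pi * i / _GOLDEN
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def gauss_sphere_quadrature(n_polar: int = 16, n_azimuth: int = 32):
    """Product quadrature on the sphere: Gauss–Legendre in cos(theta) times
    a uniform trapezoid rule in azimuth.

    Exact for spherical polynomials (hence spherical harmonics) up to degree
    ``min(2 n_polar - 1, n_azimuth - 1)``.  Returns ``(points, weights)``
    with ``points`` of shape ``(n_polar * n_azimuth, 3)`` and weights
    summing to ``4 pi``.
    """
    x, wx = np.polynomial.legendre.leggauss(n_polar)  # x = cos(theta)
    phi = 2 * np.pi * np.arange(n_azimuth) / n_azimuth
    wphi = 2 * np.pi / n_azimuth
    ct = x[:, None] * np.ones(n_azimuth)[None, :]
    st = np.sqrt(np.maximum(0.0, 1 - ct * ct))
    pts = np.stack([st * np.cos(phi)[None, :],
                    st * np.sin(phi)[None, :],
                    ct], axis=-1).reshape(-1, 3)
    w = (wx[:, None] * wphi * np.ones(n_azimuth)[None, :]).reshape(-1)
    return pts, w


def truncated_icosahedron_faces() -> np.ndarray:
    """Unit vectors through the 32 face centers of the truncated icosahedron.

    The 12 pentagonal faces point along the icosahedron vertices and the 20
    hexagonal faces along the icosahedron face centers (equivalently the
    dodecahedron vertices).  A classic near-uniform orientation grid for
    discrete-directions reconstructions.
    """
    g = _GOLDEN
    pent = []
    for a, b in [(1.0, g)]:
        for sa in (1, -1):
            for sb in (1, -1):
                pent += [(0, sa * a, sb * b), (sa * a, sb * b, 0), (sb * b, 0, sa * a)]
    hexa = [(sx, sy, sz) for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)]
    for sa in (1, -1):
        for sb in (1, -1):
            hexa += [(0, sa / g, sb * g), (sa / g, sb * g, 0), (sb * g, 0, sa / g)]
    pts = np.array(pent + hexa, dtype=float)
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)
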