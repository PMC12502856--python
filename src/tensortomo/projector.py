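"""John transform through the voxel grid: Joseph-style forward projector and
its exact adjoint.

The spatial part of the tensor-tomography forward model sums, for every
raster-scan position, the contributions of all voxels in the path of the
pencil beam.  The beam-voxel overlap coefficients ``P[sjk, xyz]`` lie in
``[0, 1]`` and vanish for voxels the beam does not intersect.  They are
realized implicitly by Joseph's method: the ray is marched in unit steps
along the dominant component of the rotated beam direction and the field is
bilinearly interpolated in the transverse plane.  The interpolation weights
are the overlap coefficients themselves, so every entry stays within
``[0, 1]``; the line integral is accumulated in units of voxel planes
traversed.

The forward and adjoint operators are built from one and the same sparse
weight list, so the adjoint is the exact transpose of the forward operator
(``<A x, y> == <x, A^T y>`` to round-off) and gradient-based optimization
sees a true gradient.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .geometry import Geometry, rotation_matrix
from .basis_sets import SegmentResponse

__all__ = ["forward", "adjoint", "projection_matrix", "sirt_preconditioners"]

# Bounded FIFO cache of assembled per-projection matrices.  Geometry objects
# are mutable (alignment updates the offsets in place), so the key digests
# the full geometry state rather than the object identity.
_MATRIX_CACHE: dict = {}
_MATRIX_CACHE_MAX = 256  # ~400 MB worst case at 32^3 grids


def _geometry_key(geometry: Geometry, s: int) -> bytes:
    parts = [
        geometry.p_direction, geometry.j_direction, geometry.k_direction,
        np.array([geometry.inner_angles[s], geometry.outer_angles[s],
                  geometry.j_offsets[s], geometry.k_offsets[s],
                  geometry.voxel_size, geometry.scan_step]),
        geometry.inner_axis, geometry.outer_axis,
        np.array(geometry.volume_shape + geometry.projection_shape, dtype=float),
    ]
    return b"".join(np.ascontiguousarray(p, dtype=float).tobytes() for p in parts)


def projection_matrix(geometry: Geometry, s: int) -> sparse.csr_matrix:
    """Sparse spatial system-matrix block for projection ``s``.

    Shape ``(J * K, X * Y * Z)``; row ``j * K + k`` holds the beam-overlap
    weights of the ray at raster position ``(j, k)``, voxels flattened in C
    order.  Per-projection alignment offsets shift the ray origins by
    sub-pixel amounts in the scan plane.
    """
    key = _geometry_key(geometry, s)
    cached = _MATRIX_CACHE.get(key)
    if cached is not None:
        return cached
    X, Y, Z = geometry.volume_shape
    J, K = geometry.projection_shape
    a = geometry.voxel_size
    b = geometry.scan_step
    R = rotation_matrix(geometry, s)
    n = R.T @ geometry.p_direction
    jv = R.T @ geometry.j_direction
    kv = R.T @ geometry.k_direction

    jj, kk = np.meshgrid(np.arange(J), np.arange(K), indexing="ij")
    r0 = (((jj - (J - 1) / 2 + geometry.j_offsets[s]) * b)[..., None] * jv
          + ((kk - (K - 1) / 2 + geometry.k_offsets[s]) * b)[..., None] * kv)
    r0 = r0.reshape(-1, 3)

    d = int(np.argmax(np.abs(n)))
    if abs(n[d]) < 1e-12:
        raise ValueError("beam direction has zero length along every axis")
    u_ax, v_ax = [ax for ax in range(3) if ax != d]
    shape = geometry.volume_shape
    nd, nu, nv = shape[d], shape[u_ax], shape[v_ax]

    planes = np.arange(nd)
    pos = (planes - (nd - 1) / 2) * a
    t = (pos[:, None] - r0[None, :, d]) / n[d]                  # (nd, JK)
    fu = (r0[None, :, u_ax] + t * n[u_ax]) / a + (nu - 1) / 2
    fv = (r0[None, :, v_ax] + t * n[v_ax]) / a + (nv - 1) / 2
    i0 = np.floor(fu).astype(np.int64)
    j0 = np.floor(fv).astype(np.int64)
    wu = fu - i0
    wv = fv - j0

    ray = np.broadcast_to(np.arange(J * K)[None, :], t.shape)
    plane = np.broadcast_to(planes[:, None], t.shape)

    rows, cols, vals = [], [], []
    for du, dv, w in ((0, 0, (1 - wu) * (1 - wv)), (1, 0, wu * (1 - wv)),
                      (0, 1, (1 - wu) * wv), (1, 1, wu * wv)):
        iu = i0 + du
        iv = j0 + dv
        valid = (iu >= 0) & (iu < nu) & (iv >= 0) & (iv < nv) & (w > 0)
        idx3 = [None, None, None]
        idx3[d], idx3[u_ax], idx3[v_ax] = plane, iu, iv
        flat = (idx3[0] * Y + idx3[1]) * Z + idx3[2]
        rows.append(ray[valid])
        cols.append(flat[valid])
        vals.append(w[valid])
    mat = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(J * K, X * Y * Z)).tocsr()
    if len(_MATRIX_CACHE) >= _MATRIX_CACHE_MAX:
        _MATRIX_CACHE.pop(next(iter(_MATRIX_CACHE)))
    _MATRIX_CACHE[key] = mat
    return mat


def _check_field(field: np.ndarray, geometry: Geometry) -> np.ndarray:
    field = np.asarray(field, dtype=float)
    if field.shape[:3] != geometry.volume_shape or field.ndim != 4:
        raise ValueError(
            f"field shape {field.shape} does not match volume "
            f"{geometry.volume_shape} + channel axis")
    return field


def forward(field: np.ndarray, geometry: Geometry) -> np.ndarray:
    """Project a coefficient field ``(X, Y, Z, N)`` to ``(S, J, K, N)``.

    Channels are independent: each is line-integrated along the beam for
    every projection and raster position.
    """
    field = _check_field(field, geometry)
    X, Y, Z, N = field.shape
    J, K = geometry.projection_shape
    S = geometry.n_projections
    flat = field.reshape(-1, N)
    out = np.empty((S, J, K, N))
    for s in range(S):
        out[s] = (projection_matrix(geometry, s) @ flat).reshape(J, K, N)
    return out


def adjoint(projections: np.ndarray, geometry: Geometry) -> np.ndarray:
    """Exact transpose of :func:`forward`: ``(S, J, K, N) -> (X, Y, Z, N)``."""
    projections = np.asarray(projections, dtype=float)
    S = geometry.n_projections
    J, K = geometry.projection_shape
    if projections.shape[:3] != (S, J, K) or projections.ndim != 4:
        raise ValueError(
            f"projections shape {projections.shape} does not match "
            f"({S}, {J}, {K}) + channel axis")
    N = projections.shape[3]
    X, Y, Z = geometry.volume_shape
    out = np.zeros((X * Y * Z, N))
    for s in range(S):
        out += projection_matrix(geometry, s).T @ projections[s].reshape(-1, N)
    return out.reshape(X, Y, Z, N)


def sirt_preconditioners(geometry: Geometry, basis_response: SegmentResponse,
                         eps_rel: float = 1e-12):
    """Voxel- and data-space SIRT weights from the full system matrix.

    Returns ``(C, R)`` where ``R[s, j, k, c]`` is the reciprocal of the
    row sum and ``C[x, y, z, i]`` the reciprocal of the column sum of the
    (absolute-valued) system matrix ``A = B * P``, computed matrix-free by
    applying the projector and the basis map to all-ones vectors.  Sums
    below ``eps_rel`` times the largest sum are excluded (weight 0), which
    guards rays that miss the volume and voxels no ray touches.
    """
    B = np.abs(basis_response.B)  # (S, C, N)
    S, C, N = B.shape
    X, Y, Z = geometry.volume_shape
    J, K = geometry.projection_shape

    # Row sums: path length of each ray times the basis-row sums.
    lengths = forward(np.ones((X, Y, Z, 1)), geometry)[..., 0]   # (S, J, K)
    row_sums = lengths[..., None] * B.sum(axis=2)[:, None, None, :]
    # Column sums: adjoint of the basis-column sums, constant over the scan.
    col_input = np.broadcast_to(B.sum(axis=1)[:, None, None, :], (S, J, K, N))
    col_sums = adjoint(np.ascontiguousarray(col_input), geometry)

    def invert(sums):
        out = np.zeros_like(sums)
        mask = sums > eps_rel * max(sums.max(), np.finfo(float).tiny)
        out[mask] = 1.0 / sums[mask]
        return out

    return invert(col_sums), invert(row_sums)
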