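"""Independent brute-force oracles used to validate the package numerics.

These are deliberately slow, scalar-loop implementations written separately
from the package code paths they check.
"""

import numpy as np
from scipy.spatial.transform import Rotation


def dense_joseph_matrix(geometry, s):
    """Explicitly assembled dense spatial system matrix for projection ``s``.

    Plain per-ray, per-plane scalar loops: for every raster position the ray
    is stepped through the voxel planes perpendicular to the dominant
    component of the rotated beam, and the bilinear interpolation weights
    are accumulated into a dense ``(J * K, X * Y * Z)`` matrix.
    """
    X, Y, Z = geometry.volume_shape
    J, K = geometry.projection_shape
    a, b = geometry.voxel_size, geometry.scan_step
    R = (Rotation.from_rotvec(geometry.outer_angles[s] * geometry.outer_axis)
         * Rotation.from_rotvec(geometry.inner_angles[s] * geometry.inner_axis)
         ).as_matrix()
    n = R.T @ geometry.p_direction
    jv = R.T @ geometry.j_direction
    kv = R.T @ geometry.k_direction
    shape = geometry.volume_shape
    d = int(np.argmax(np.abs(n)))
    u_ax, v_ax = [ax for ax in range(3) if ax != d]
    nd, nu, nv = shape[d], shape[u_ax], shape[v_ax]
    A = np.zeros((J * K, X * Y * Z))
    for j in range(J):
        for k in range(K):
            r0 = ((j - (J - 1) / 2 + geometry.j_offsets[s]) * b * jv
                  + (k - (K - 1) / 2 + geometry.k_offsets[s]) * b * kv)
            for plane in range(nd):
                t = ((plane - (nd - 1) / 2) * a - r0[d]) / n[d]
                fu = (r0[u_ax] + t * n[u_ax]) / a + (nu - 1) / 2
                fv = (r0[v_ax] + t * n[v_ax]) / a + (nv - 1) / 2
                iu, iv = int(np.floor(fu)), int(np.floor(fv))
                wu, wv = fu - iu, fv - iv
                for du, dv, w in ((0, 0, (1 - wu) * (1 - wv)),
                                  (1, 0, wu * (1 - wv)),
                                  (0, 1, (1 - wu) * wv),
                                  (1, 1, wu * wv)):
                    cu, cv = iu + du, iv + dv
                    if 0 <= cu < nu and 0 <= cv < nv and w > 0:
                        idx = [0, 0, 0]
                        idx[d], idx[u_ax], idx[v_ax] = plane, cu, cv
                        flat = (idx[0] * Y + idx[1]) * Z + idx[2]
                        A[j * K + k, flat] += w
    return A


def dense_system_matrix(geometry, basis_response):
    """Full dense system matrix: rows ordered (s, j, k, c), columns
    (voxel, basis function)."""
    B = basis_response.B  # (S, C, N)
    S, C, N = B.shape
    blocks = []
    for s in range(S):
        P = dense_joseph_matrix(geometry, s)    # (JK, V)
        blocks.append(np.einsum("rv,cn->rcvn", P, B[s]).reshape(
            P.shape[0] * C, P.shape[1] * N))
    return np.concatenate(blocks, axis=0)
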