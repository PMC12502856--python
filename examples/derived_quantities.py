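"""Derived per-voxel quantities of a reciprocal-space-map field.

Builds single-voxel coefficient fields for the two scattering archetypes —
polar caps (scattering concentrated along an axis) and an equatorial band
(fiber scattering) — and prints their mean intensity, second-moment
eigenvalues, fractional anisotropy and main orientation.
"""

import numpy as np

import tensortomo as tt
from tensortomo._sphere import gauss_sphere_quadrature


def project_onto_basis(basis, W):
    """Expansion coefficients of a function W(q) given on a quadrature grid."""
    pts, w = gauss_sphere_quadrature(8, 18)
    values = basis.evaluate(pts)
    return (values * w[:, None]).T @ W(pts)


def main():
    basis = tt.SphericalHarmonics(ell_max=4)
    axis = np.array([0.0, 0.0, 1.0])

    shapes = {
        "isotropic":       lambda q: np.ones(len(q)),
        "polar caps":      lambda q: 3.0 * (q @ axis) ** 2,
        "equatorial band": lambda q: 1.5 * (1.0 - (q @ axis) ** 2),
    }
    for name, W in shapes.items():
        field = project_onto_basis(basis, W).reshape(1, 1, 1, -1)
        maps = tt.compute_derived_maps(
            field, basis,
            orientation_mode=("equatorial_band" if "band" in name
                              else "polar_peaks"))
        lam = maps.eigenvalues[0, 0, 0]
        print(f"{name:16s} mean intensity {maps.mean_intensity[0,0,0]:.3f}  "
              f"eigenvalues [{lam[0]:.2f} {lam[1]:.2f} {lam[2]:.2f}]  "
              f"FA {maps.fractional_anisotropy[0,0,0]:.3f}  "
              f"orientation {np.round(maps.main_orientation[0,0,0], 3)}")
    print("\nAll three shapes share unit mean intensity; FA separates them "
          "by eigenvalue dispersion, and the main orientation recovers the "
          "z symmetry axis (largest eigenvector for polar scattering, "
          "smallest for an equatorial band).")


if __name__ == "__main__":
    main()
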