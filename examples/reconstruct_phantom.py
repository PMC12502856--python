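"""Reconstruct a synthetic fiber phantom and compare against ground truth.

Builds a 16^3 phantom of anisotropic voxels (equatorial-band scattering
about a smoothly varying fiber axis), simulates a 60-projection acquisition
with 8 detector segments, reconstructs with the spherical-harmonic SIGTT
pipeline and reports how well coefficients and orientations are recovered.
"""

import numpy as np

import tensortomo as tt


def main():
    spec = tt.PhantomSpec()  # 16^3, uniaxial fiber, SH band limit 4
    field, axis, support = tt.make_phantom(spec)
    geometry = tt.acquisition_geometry(spec)
    segments = tt.DetectorSegments.evenly_spaced(spec.n_segments)
    stack = tt.simulate_experiment(field, geometry, segments, spec.basis)
    print(f"phantom: {support.sum()} support voxels, "
          f"{geometry.n_projections} projections, "
          f"{segments.n_segments} detector segments")

    rec = tt.run_sigtt(stack, geometry, segments, ell_max=4,
                       laplacian_weight=0.0, max_iter=400, stopping=1e-14)
    trace = rec.provenance["loss_trace"]
    print(f"SIGTT: loss {trace[0]:.3e} -> {trace[-1]:.3e} "
          f"in {len(trace)} L-BFGS iterations")

    r = np.corrcoef(rec.coefficients[support].ravel(),
                    field[support].ravel())[0, 1]
    T = tt.second_moment(rec.coefficients, spec.basis)
    orientation = tt.main_orientation(T, mode="equatorial_band")
    cosang = np.abs(np.sum(orientation * axis, axis=-1))
    err_deg = np.degrees(np.arccos(np.clip(cosang, 0, 1)))
    frac = np.mean(err_deg[support] <= 5.0)
    print(f"coefficient correlation with ground truth: {r:.4f}")
    print(f"voxels with orientation error <= 5 deg:    {100 * frac:.1f} %")
    print("(correlation near 1 and a high orientation fraction mean the "
          "tensor field was faithfully recovered from noiseless data)")


if __name__ == "__main__":
    main()
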