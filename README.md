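# tensortomo

Tensor tomography of scanning small- and wide-angle X-ray scattering
(SAXS/WAXS) data: reconstruct, per voxel, a spherical shell of the local
reciprocal-space map — the direction-resolved scattering intensity
`W(q̂)` — from azimuthally regrouped projection stacks.

Scanning SAXS/WAXS raster-scans a sample through a focused beam while a
two-circle goniometer (rotation α, tilt β) varies its orientation, and the
detector is split into azimuthal segments. The measured intensities obey
the linear model

    I[s,j,k,c] = Σ_i B[s,c,i] Σ_xyz P[sjk,xyz] c_xyzi ,

where `P ∈ [0,1]` are beam–voxel overlap coefficients (a John transform
along the beam), `B[s,c,i]` is the average of basis function `f_i` over the
arc of directions probed by detector segment `c` at rotation `s`, and
`c_xyzi` are the unknown per-voxel expansion coefficients of
`W(q̂) = Σ_i c_i f_i(q̂)`. Reconstruction minimizes
`ρ(A c − I) + μ‖D c‖' + …` for a squared or Huber data norm and optional
regularizers. The intended users are beamline scientists and researchers
analyzing nanostructure orientation in hierarchical materials (bone,
cellulose, polymers) who need the full chain from measured HDF5 projection
stacks to orientation and anisotropy maps.

## Features

* **Geometry** — configurable beam/scan/detector unit vectors, two-circle
  goniometer rotations, detector segmentation at small or finite
  scattering angle.
* **Data I/O** — the standard HDF5 projection-stack layout (per-projection
  `data`, `diode`, `weights`, angles and offsets plus geometry vectors),
  transmission normalization, and self-describing reconstruction output
  files.
* **Projector** — Joseph-type bilinear John transform with an exactly
  matched adjoint (dot-product identity to 1e-10).
* **Basis sets** — real even-degree spherical harmonics, nearest-neighbor
  indicators and spherical Gaussian kernels, with adaptive or
  central-angle detector-segment responses.
* **Pipelines** — SIRT, MITRA (regularizers + Nesterov momentum), SIGTT
  (spherical harmonics + Laplacian + L-BFGS-B) and discrete directions
  (independent scalar SIRTs).
* **Alignment** — iterative phase-matching (cross-correlation with
  sub-pixel Fourier upsampling) recovery of per-projection offsets from
  transmission sinograms.
* **Derived maps** — mean intensity, second-moment tensor, eigensystem,
  main orientation (polar-cap or equatorial-band rule) and fractional
  anisotropy.
* **Phantoms** — seeded synthetic experiments (textures, noise models,
  injected misalignment) for validation and planning.

## Worked example

```python
import numpy as np
import tensortomo as tt

spec = tt.PhantomSpec()                      # 16^3 fiber phantom, SH l_max = 4
field, axis, support = tt.make_phantom(spec)
geometry = tt.acquisition_geometry(spec)     # 60 projections (20 x 3 tilts)
segments = tt.DetectorSegments.evenly_spaced(8)   # half circle, SAXS
stack = tt.simulate_experiment(field, geometry, segments, spec.basis)

rec = tt.run_sigtt(stack, geometry, segments, ell_max=4,
                   max_iter=400, stopping=1e-14)
r = np.corrcoef(rec.coefficients[support].ravel(), field[support].ravel())[0, 1]

T = tt.second_moment(rec.coefficients, spec.basis)
v = tt.main_orientation(T, mode="equatorial_band")
err = np.degrees(np.arccos(np.clip(np.abs(np.sum(v * axis, -1)), 0, 1)))
print(f"coefficient correlation {r:.4f}; "
      f"{100 * np.mean(err[support] <= 5):.1f} % of voxels within 5 deg")
```

Running this (`python examples/reconstruct_phantom.py`) prints

```
phantom: 1328 support voxels, 60 projections, 8 detector segments
SIGTT: loss 1.329e+06 -> 1.686e-01 in 400 L-BFGS iterations
coefficient correlation with ground truth: 0.9983
voxels with orientation error <= 5 deg:    99.7 %
```

i.e. from noiseless synthetic data the spherical-harmonic reconstruction
recovers the per-voxel coefficients almost perfectly, and the fiber axis
extracted from the second-moment tensor (smallest eigenvector, since fiber
scattering forms an equatorial band) matches the ground-truth orientation
field in essentially every support voxel. The other scripts in `examples/`
demonstrate offset recovery by phase-matching alignment, the derived
per-voxel quantities, and the HDF5 round-trip workflow.

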