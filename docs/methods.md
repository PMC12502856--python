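# Methods

## The reconstruction problem

Scanning small- and wide-angle X-ray scattering tensor tomography (SAXS/
WAXS-TT) raster-scans a sample through a pencil beam while rotating and
tilting it on a two-circle goniometer. Each detector image is azimuthally
regrouped into `C` segments at fixed scattering angle, so one q bin of the
experiment is a 4D array `D[s, j, k, c]` over goniometer settings `s`,
raster positions `(j, k)` and segments `c`. The reconstruction target is a
voxel map in which every voxel carries a function `W(q̂)` on the unit
sphere — one spherical shell of the local reciprocal-space map — expanded
in a finite basis,

    W_xyz(q̂) = Σ_i c_xyzi f_i(q̂),

and the unknowns are the coefficients `c_xyzi`.

The forward model composes two linear maps:

1. **Spatial projection (John transform).** The beam at setting `s` and
   raster position `(j, k)` illuminates a line through the voxel grid;
   beam–voxel overlap coefficients `P[sjk, xyz] ∈ [0, 1]` sum the voxel
   contributions along the path, with `P = 0` for voxels the beam misses.
   Per-projection offsets `Δj_s, Δk_s` (parasitic stage movement) shift the
   ray origins in the scan plane by sub-pixel amounts.
2. **Detector response.** Each segment probes the average of `W` over the
   arc of sample-frame directions `q̂(φ) = R_sᵀ [cos θ (cos φ q̂₀ +
   sin φ q̂₉₀) − sin θ p̂]`, giving the response matrix
   `B[s, c, i] = (1/Δφ) ∫ f_i(q̂(φ)) dφ`.

The measured intensity model is `I[s,j,k,c] = Σ_i B[s,c,i] Σ_xyz
P[sjk,xyz] c_xyzi`; both factors depend on `s`, so the system matrix does
not factorize into a projection part and a reciprocal-space part.
Reconstruction minimizes `ρ(A c − I)` plus optional regularization terms
`μ‖D c‖'`.

## Projector discretization

The John transform follows Joseph's interpolating ray-driven scheme: the
ray is marched in unit steps along the voxel planes perpendicular to the
dominant component of the rotated beam direction, and the field is
bilinearly interpolated in the two transverse axes at each plane. The
interpolation weights are the overlap coefficients themselves; they lie in
`[0, 1]` by construction (four weights per plane summing to 1 for rays
inside the grid), and out-of-grid samples contribute nothing. The line
integral is therefore accumulated in units of voxel planes traversed — an
axis-aligned through-ray of an `N³` grid integrates a constant-1 field to
exactly `N`. We deliberately do not rescale each step by the inverse
dominant beam component: that variant measures metric path length but
pushes oblique coefficients up to √3, breaking the `P ≤ 1` overlap bound
that the model is stated with. Any global scale difference between the two
conventions is absorbed by the coefficients.

Voxel and scan grids are 0-based and symmetric: voxel centers sit at
`(x − (N_x − 1)/2)·a` and ray origins at `(j − (J − 1)/2 + Δj_s)·b` along
the rotated scan axes, with voxel size `a` and scan step `b` both 1 by
default (reconstruction matched to the raster).

Forward and adjoint are built from one sparse per-projection matrix
(assembled on demand and kept in a bounded cache keyed on the geometry
state), so the adjoint is the exact transpose and the dot-product identity
`⟨Ax, y⟩ = ⟨x, Aᵀy⟩` holds to round-off — gradient-based optimizers see a
true gradient. An independent scalar-loop dense ray tracer in the test
suite defines the reference behavior.

## Basis sets

* **Spherical harmonics (SH)** — real, orthonormal, ordered by degree `ℓ`
  ascending and order `m` from `−ℓ` to `+ℓ`. Scattered intensity obeys
  Friedel symmetry `W(q̂) = W(−q̂)`, so only even degrees are included by
  default (sufficient for half-circle SAXS detector coverage); odd degrees
  can be enabled for full-circle WAXS data. The band limit `ℓ_max` sets the
  angular resolution (~`2π/ℓ_max`).
* **Nearest-neighbor indicators (NN)** — cells of an orientation grid under
  antipodally symmetrized geodesic distance; the workhorse of
  discrete-directions reconstructions. The default grid is a hemispherical
  Fibonacci lattice; a truncated-icosahedron face-center table is provided,
  and arbitrary user grids are accepted.
* **Gaussian kernels (GK)** — `exp(−d²/2σ²)` of the geodesic angle `d` to
  the nearer of the two antipodal centers, width `σ` in radians (default
  0.3). Kernels peak at 1 and are not normalized to unit integral; the
  normalization is absorbed into the coefficients.

Segment responses are computed either by adaptive Simpson quadrature
(absolute tolerance 1e-6) or by evaluating at the central angle of each
segment — the fast approximation that is also the generator's default, so
simulated data match the model exactly. At the jump discontinuities of the
NN indicators the adaptive error estimate cannot converge; subintervals
narrower than 1e-9 rad are accepted as-is, bounding the work while keeping
their contribution below tolerance.

## Derived quantities

Per voxel: the mean (isotropic) intensity `(1/4π)∮W dΩ` (analytic in the
degree-0 SH coefficient; mesh quadrature otherwise); the second-moment
tensor `T_ij = ∮ W q_i q_j dΩ`, evaluated on a Gauss–Legendre × uniform
product grid that is exact for band-limited fields (only degrees 0 and 2
contribute, so this is a closed form in the coefficients); its eigensystem
(descending); the main orientation (largest eigenvector for polar-cap
scattering, smallest for equatorial-band/fiber scattering, sign fixed so
the leading component is positive, near-degenerate pairs flagged); and the
fractional anisotropy

    FA = √(3/2) · √Σ(λ_i − λ̄)² / √Σλ_i²,

0 for isotropic and 1 for single-direction scattering, clipped to [0, 1]
for positive-semidefinite tensors and snapped to exactly 0 when the
eigenvalue dispersion is below 1e-13 relative (round-off). `T` is left
unnormalized by default — FA and orientation are scale-free — with a
`normalize=True` variant dividing by `∮W dΩ`. A relative-anisotropy
measure (spherical std/mean) is provided alongside.

## Optimization

Weights multiply residuals before the loss, so weight 0 removes a
measurement entirely. Data norms: squared and Huber (δ = 1 default).
Regularizers: squared norm of a reflective 6-neighbor finite-difference
Laplacian (symmetric, constants unpenalized); total variation as
Huber(δ = 1e-2) of forward-difference gradients (no difference across the
far boundary); L1, L2 and elementwise Huber norms, each with an optional
per-coefficient diagonal weight. With SH bases the L1/Huber coefficient
norms are not rotational invariants and trigger a runtime warning.
Optimizers: fixed-step gradient descent with optional Nesterov momentum
(extrapolation factor `t/(t+3)`), and L-BFGS-B (scipy) with a
relative-loss-change stop.

## Pipelines

* **SIRT** — preconditioned gradient descent on row-sum-weighted least
  squares with unit step: `x ← x + C Aᵀ R (b − A x)`, where `R` and `C`
  are reciprocal row/column sums of `|A|`, computed matrix-free by applying
  the projector and the (absolute-valued) detector response to all-ones
  vectors. Absolute values matter: signed SH rows can cancel. Sums below
  1e-12 of the maximum are excluded. Semi-convergent; early stopping
  regularizes (default 20 iterations).
* **MITRA** — the same update extended with arbitrary regularizer terms
  and optional Nesterov momentum; with neither, it is iterate-for-iterate
  identical to SIRT.
* **SIGTT** — SH basis, squared loss, optional Laplacian weight, minimized
  by L-BFGS-B from zero (the problem is convex; zero init makes runs
  deterministic). Default stop: relative loss change below 1e-4. Driving a
  noiseless 16³/60-projection fit down to 1e-8 of the initial loss takes
  roughly 1500 iterations — the default cap of 50 targets interactive use.
* **DD (discrete directions)** — one scalar SIRT per NN grid direction.
  Measurements `(s, c)` are assigned to direction `m` when the segment arc
  overlaps cell `m` (`B[s,c,m] > 0`) and weighted by the arc fraction
  `B[s,c,m]`, conserving signal for segments that straddle cell borders.
  Unprobed directions yield zeroed channels with a warning.

All pipelines leave their inputs untouched and record a loss trace in the
output provenance.

## Alignment

Phase matching estimates the per-projection offsets from a scalar sinogram
(transmission, or an azimuthally averaged signal): center-of-mass
pre-centering, then a reconstruct–reproject loop in which each measured
projection is registered against its synthetic counterpart by
cross-correlation with 10× Fourier-upsampled sub-pixel refinement
(`skimage.registration.phase_cross_correlation`). Offset updates are
damped by 0.8 to stabilize the loop; the mean offset per axis is
constrained to zero, because a common translation of all projections is a
gauge freedom the data cannot determine. Defaults: tolerance 0.1 px on the
largest offset change, 20 outer iterations, 10 SIRT iterations per
reconstruction. A greedy projection-ordering helper sorts settings by
beam-direction proximity for inspecting offset traces.

## Synthetic data

The generator emulates a rotation + tilt acquisition: inner angles uniform
over a full turn (20 steps by default) crossed with tilts {0°, 20°, 40°},
i.e. 60 projections, 8 half-circle detector segments, on a 16³ grid — the
default conditions under which recovery is validated. Phantoms are
spherical (or concentric-shell) supports with unit density and a smoothly
varying symmetry axis; per-voxel maps interpolate between isotropic and a
pure archetype with the anisotropy parameter `A ∈ [0, 1]`:
equatorial band `(1−A) + A·(3/2)(1 − (q̂·û)²)` for fiber textures, polar
caps `(1−A) + A·3(q̂·û)²` for shells — both with unit spherical mean.
Projection onto SH uses exact quadrature; onto NN/GK a least-squares fit
on a 1000-node sphere mesh. Transmission images follow a Beer–Lambert law
with the isotropic intensity as density proxy (minimum transmission ≈ 0.3)
so alignment sees realistic contrast. Gaussian noise is specified relative
to the mean model intensity; Poisson noise via a counts scale; negative
intensities are clipped to zero with a warning. All randomness derives
from a single seed.

What the phantoms do **not** emulate: physically quantitative scattering
cross-sections and form factors, detector solid-angle/polarization
corrections (assumed already applied upstream), beam divergence and finite
beam width beyond the bilinear footprint, multi-q shells, and non-smooth
orientation fields. Passing recovery tests therefore demonstrates the
correctness and self-consistency of the forward model and solvers, not
performance on every experimental pathology.

## Numerical choices and limitations

* Rotations compose as outer(tilt) ∘ inner(rotation); the geometry
  defaults put the beam along x, scan axes along y and z, the inner axis
  along z and the outer axis along y — all configurable, including the
  sign of the out-of-detector-plane tilt of the scattering vector at
  finite scattering angle (`tilt_sign`).
* Angles are radians everywhere in memory and on disk; the loader offers a
  degrees flag and accepts segment centers in place of boundaries.
* Degenerate eigenpairs (gap < 1e-9 × trace) get a deterministic
  tie-break and an ambiguity flag; orientation extraction is meaningless
  where the rank-2 component vanishes (e.g. cubic Bragg textures).
* Problem sizes in the validation suite (16³ reconstruction grids, 32³
  alignment grids, 60 projections) were chosen so the full suite runs on a
  single CPU core in a few minutes while still exercising every claim at
  meaningful scale.
* The axially symmetric zonal-harmonics workflow (nonlinear forward
  model), optical-flow alignment, and GPU/asynchronous execution are out
  of scope.
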