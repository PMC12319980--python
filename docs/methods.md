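# Methods

`anisofield` models the physics chain of transcranial electric stimulation
(tES) experiments that combine electric-field simulation with magnetic
resonance electrical impedance tomography (MREIT): injected scalp currents
set up a quasi-static current flow through the head, whose electric field
|E| is the presumed physiological dose and whose current density J produces
a tiny magnetic field whose z-component, B_z, is measurable by MRI. The
package implements that chain on structured voxel phantoms, end to end:
diffusion-to-conductivity tensor mapping, anisotropic forward solve,
Biot–Savart B_z, polynomial-chaos uncertainty quantification, conductivity
optimization against B_z data, and DT-MREIT voxel-wise conductivity
reconstruction.

## Volume conductor model

The quasi-static current-flow problem is

    div( sigma(r) grad phi(r) ) = 0,     J = -sigma grad phi,

with a symmetric positive-definite 3x3 conductivity tensor sigma per voxel.
It is discretized with node-based trilinear hexahedral finite elements on
the uniform voxel grid; the 8x8 element stiffness matrix is assembled from
closed-form component integrals contracted with the element's full tensor,
so anisotropy is represented exactly at element level. The non-conducting
exterior is excluded from assembly, which imposes the natural no-flux
boundary condition on the head surface.

Electrodes are modeled as Dirichlet patches on boundary faces, held at
+/-0.5 V; after the solve, potential and fields are rescaled so the
surface-integrated anode current equals the montage's injected current
(default 1 mA baseline-to-peak). Working under current control has one
important consequence used throughout: scaling all conductivities by a
common factor k leaves J and B_z unchanged and scales phi by 1/k. The
conductivity fit therefore identifies conductivity *ratios*; absolute
values are pinned only by the box bounds.

The symmetric positive-definite linear system is solved with
Jacobi-preconditioned conjugate gradients at a relative tolerance of 1e-8
(far below the ~1% field-accuracy targets). A sparse-LU path exists but CG
was consistently faster at every grid size used here, so it is the default.
E is evaluated per element as the trilinear gradient at the element center
and J = sigma E; the discrete statement of charge conservation is the nodal
residual of the stiffness system, reported as a fraction of the injected
current.

## Diffusion-to-conductivity mapping

Two mappings convert water diffusion tensors D (mm^2/s) to conductivity
tensors (S/m), both preserving eigenvectors:

* **direct**: sigma = s D with one global scale
  s = (s_WM sigma_WM^iso + s_GM sigma_GM^iso) / (s_WM^2 + s_GM^2), where
  s_WM, s_GM are the per-tissue voxel averages of the geometric mean of
  the eigenvalues of D. s is the least-squares fit matching both tissues'
  mean conductivities jointly to the literature values; it is invariant to
  global rescaling of D. The per-tissue averages use each tissue's own
  voxel count.
* **volume-normalized**: per voxel,
  sigma_i = d_i / (d1 d2 d3)^(1/3) * sigma_tissue^iso, which preserves the
  geometric-mean conductivity of every voxel exactly (machine precision, a
  tested invariant).

Default isotropic conductivities and the uniform uncertainty ranges are
shipped in `data/tissues.yaml` (S/m): WM 0.126 [0.1, 0.4], GM 0.275
[0.1, 0.6], CSF 1.654 [0.8, 1.8], spongy bone 0.025 [0.015, 0.040],
compact bone 0.008 [0.003, 0.012], scalp 0.465 [0.2, 1.0]; electrode
rubber 29.0 and gel 1.0 are available for explicit electrode layers.

The ground-truth conductivity tensor image (CTI) for reconstruction
benchmarks scales D linearly per region so region-average geometric-mean
conductivities match the literature values, sets CSF isotropic, and then
smooths each tensor component with a small Gaussian (default 1 mm FWHM,
interpreted as FWHM per the neuroimaging convention) inside the brain+CSF
mask with edge-renormalized kernels. Smoothing avoids step conductivity
changes that produce discontinuous current densities; it slightly shifts
region averages, and any marginally indefinite tensors it creates at
boundaries are projected back to SPD by eigenvalue clamping (counts
logged).

## Magnetic fields

B_z is computed from J with the Biot–Savart law discretized at voxel
centers and evaluated by zero-padded (2x per axis) FFT convolution; the
singular self-voxel term is zero by symmetry for piecewise-constant J. J_z
does not contribute to B_z. A direct O(N*M) summation with the same kernel
serves as the oracle for the fast path, and linearity in J and in the
injected current are tested invariants. Cable stray fields are computed
from polyline paths with the closed-form finite-segment formula and
subtracted from synthetic measurements (`stray_correct`), matching how
measured MREIT maps are corrected before use. Units: J in A/m^2, spacing
converted to metres, B_z reported in nT.

## Uncertainty quantification (polynomial chaos)

Tissue conductivities are modeled as independent uniform random variables
on the literature ranges. A quantity of interest q(sigma) (the |E| values
on the mid-GM shell, or the B_z values in a masked slice) is expanded in a
tensor-product basis of Legendre polynomials, orthonormal under the uniform
priors mapped to [-1,1]^d, truncated by total degree. Coefficients are fit
by least squares (ridge 1e-12 for conditioning) on Latin-hypercube samples,
2x oversampled relative to the basis size; forward evaluations are cached
and reused as the degree grows. The total degree increases until a 10-fold
cross-validated normalized RMSE reaches the tolerance (default 0.01), else
the trainer warns at the degree cap. Orthonormality makes the statistics
coefficient-level identities: the mean is the constant coefficient, the
variance the sum of squared non-constant coefficients, and first-order /
total-order Sobol indices are coefficient-group ratios. Exactness on
polynomial maps, closed-form uniform moments, closed-form Sobol indices of
additive and product maps, and agreement with brute-force Monte Carlo of
the phantom solver are all pinned by tests.

For the anisotropic mapping schemes, sampled GM/WM conductivities are
converted to tensor fields through the corresponding mapping before each
forward solve, so the surrogate sees the anisotropy model end to end.

Summary metrics (percent): relative STD = sum(STD_i)/sum(|mean_i|) x 100
over a region, and the relative difference between two fields, reported by
default in the homogeneous root form 100*sqrt(sum((a-b)^2)/sum(b^2)) (a
uniform 10% scaling reads as 10%), with the plain ratio-of-sums-of-squares
form available behind a flag. The B_z mismatch delta_Bz used as the
optimization objective is the ratio form (monotone-equivalent to the root
form, so the minimizer is unchanged).

## Conductivity optimization

`optimize_conductivities` minimizes delta_Bz over per-tissue conductivities
with SLSQP under the box bounds and, when GM and WM are both free, the
ordering constraint sigma_GM - sigma_WM >= 1e-4 S/m. The number of starts
and start values are configuration (default: 8 Latin-hypercube starts);
the best feasible optimum is returned with a full trace, and the result is
contractually never worse than its own best start. The B_z-producing
function can be the forward solver or a trained surrogate; the pipelines
use the surrogate to keep the fit to seconds.

## Projected current density and DT-MREIT

Given measured B_z and a uniform-conductivity reference solve (J0, Bz0 —
the reference conductivity value is immaterial by scale invariance), the
transversal current density is

    J_rec = J0 + (1/mu0) [ d(Bz-Bz0)/dy, -d(Bz-Bz0)/dx, 0 ],

with in-plane central differences inside the mask (one-sided at the mask
boundary) and J0's z-component carried through unchanged: the method never
recovers J_z, and its accuracy rests on the z-current being unimportant.
On the z-invariant cylinder phantom that assumption holds and the
transversal error is a few percent; on head-like phantoms with substantial
J_z it degrades, which is the mechanism behind the benchmark ordering
below. The sign pattern (+d/dy, -d/dx) is the one consistent with
div(J_rec) = div(J0).

DT-MREIT assumes sigma = eta(r) D(r) with a scalar "diffusivity ratio"
map eta. Because E is curl-free, F_i = D^{-1} J_i for each of two
independent injections satisfies, per voxel in an axial plane,

    F_iy * d(log eta)/dx - F_ix * d(log eta)/dy = dF_iy/dx - dF_ix/dy,

a 2x2 system for the in-plane gradient of log eta. Voxels whose 2x2 matrix
has condition number above 1e3 are flagged and infilled from the nearest
well-conditioned neighbor; if more than 20% of the mask is ill-conditioned
the montage pair is rejected as insufficiently independent. The outermost
mask ring is excluded from the system and infilled afterwards: one-sided
derivatives of the discrete current density corrupt the rim, and because
the next step integrates the gradient, rim errors would otherwise
contaminate the entire map (removing one ring reduced the cylinder eta
error from ~27% to ~2%).

log eta is integrated from its recovered gradient g by the regularized
screened-Poisson least-squares problem

    min_u  || grad u - g ||^2 + xi || u - log eta_ext ||^2,

solved as a sparse linear system on the masked slice; eta = exp(u). The
exterior scale log eta_ext is imposed weakly through the screening term
rather than as a hard Dirichlet condition: gradient data determine u only
up to one additive constant, and a hard constant boundary trace would
contradict any spatially varying eta. As xi -> 0 the solution approaches
pure gradient integration with its mean pinned to log eta_ext; as
xi -> infinity it flattens to log eta_ext (the over-regularized "flat"
reconstruction); adding a constant to log eta_ext shifts log eta by that
constant. All three limits are pinned by tests. xi <= 0 is rejected.

The two hyperparameters (xi, log eta_ext) are tuned per case by
Nelder–Mead over (log10 xi, log eta_ext) against the ground-truth
geometric-mean conductivity, mirroring how the algorithm is benchmarked
when ground truth is available; the initial simplex spans three decades in
xi because the useful regularization regime varies by orders of magnitude
between cases.

## Synthetic phantoms — what they emulate and what they do not

The **head phantom** is a set of concentric spherical shells (scalp 60 mm,
compact bone 54, spongy bone 50, CSF 44, GM 38, WM 30; each shell at least
one voxel thick, so the spongy layer requires spacing <= 4 mm). WM
diffusion tensors are prolate with eigenvalue ratio 9:1 along a
circumferential fiber field, GM near-isotropic (1.1:1, radial), other
tissues isotropic; at every voxel the eigenvalue geometric mean equals the
tissue's mean diffusivity exactly (WM 0.7e-3, GM 0.8e-3, CSF 3.0e-3
mm^2/s, representative literature values). Electrode montages are circular
scalp patches (default 35 mm diameter, 1 mA), anterior–posterior and
right–left. The phantom preserves the layered impedance structure,
brain-anisotropy geometry, and montage asymmetry of a real head; it does
not reproduce cortical folding, fiber-tract heterogeneity, or partial
volume effects, so its anisotropy effect on the fields is stronger and
more coherent than in vivo. Passing orderings on this phantom demonstrate
that the pipeline reproduces the mechanisms, not the in-vivo effect sizes.

The **cylinder phantom** is z-invariant: an isotropic background cylinder
(radius 20 mm) with one isotropic and three anisotropic inclusions
(radius 4.5 mm; principal directions x, y, and 45 degrees; eigenvalue
ratio 5:1), with full-height lateral strip electrode pairs injecting
purely transversal currents. Tensors are smoothed with a 2 mm FWHM
Gaussian at construction, emulating the finite resolution of measured
diffusion data and avoiding current-density discontinuities at inclusion
boundaries (hard steps roughly triple the projected-current error);
smoothing preserves the inclusions' principal directions, the isotropy of
isotropic regions, SPD, and z-invariance exactly. The DT-MREIT benchmark
on it uses a region-wise eta map (background 300, isotropic inclusion 150,
anisotropic inclusions 450 (S/m)/(mm^2/s)), smoothed in log space over the
same scale so the ground truth remains an exact sigma = eta D pair.

Synthetic B_z "measurements" are forward B_z plus optional cable stray
field plus i.i.d. Gaussian noise (nT), reproducible under a fixed seed.

## Study pipelines and their design choices

* **Uncertainty analysis** (`substudy_uncertainty`): per mapping scheme
  (isotropic, direct, volume-normalized), one surrogate over the 6-tissue
  prior; outputs relative STD and mean-field differences for |E| on the
  mid-GM shell (a voxel shell halfway between CSF and WM by Euclidean
  distance transforms), |E| in the GM volume, the shell-normal E component
  (normals approximated by the radial direction of the spherical
  phantom), and B_z in the masked central slice.
* **Conductivity fit** (`substudy_fit`): the synthetic "measurement" is
  simulated from a prior-drawn individual conductivity vector — real
  subjects are not literature averages, which is exactly why fitting
  helps — using the volume-normalized mapping, deliberately outside both
  fitted families (isotropic and direct-mapped), plus Gaussian noise at a
  35% relative-error floor in the delta_Bz sense, the midpoint of the
  reported noise level of in-vivo MREIT reference scans. Both model
  families are then fit through their surrogates, giving the four
  conditions literature/optimized x isotropic/anisotropic.
* **DT-MREIT benchmark** (`substudy_dtmreit`, `cylinder_dtmreit_benchmark`):
  three input cases — exact currents from the anisotropic ground-truth CTI
  ("aniso"), currents from matched isotropic conductivities ("iso"), and
  projected currents recovered from simulated B_z ("jproj") — each with
  per-case tuned hyperparameters, evaluated on a central axial slice by
  the relative errors of the geometric-mean conductivity and of eta, plus
  per-tissue mean +/- std tables.

## Problem sizes and numerical defaults

Default analyses run the head phantom at 32^3 voxels of 4 mm (64^3 at
2 mm for higher-resolution reports) and the cylinder at 48x48x16 voxels of
1 mm; surrogate training uses total degree up to 3–5 depending on the
target tolerance. These sizes keep every pipeline in seconds to a few
minutes on one CPU while leaving all tested properties
resolution-independent or convergent (the parallel-plate and two-layer
solver checks are exact to solver tolerance at any resolution; grid
refinement monotonicity is tested).

Known limitations: structured grids cannot represent smooth anatomical
boundaries (staircase electrodes and interfaces); the Dirichlet-patch
electrode model omits electrode-electrolyte interface impedance (the
complete electrode model); the projected-current and DT-MREIT steps are
evaluated on single axial slices; no AC/transient effects (quasi-static
only); and the surrogate does not extrapolate outside the prior box.
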