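# Methods

## Model

The reconstruction solves, over the whole imaging grid,

    chi* = argmin_chi  1/2 ||w (f - d*chi)||_2^2
                       + lambda1 sum_axes ||M_G grad chi||_1
                       + lambda2 ||r (L chi)||_2^2

with all fields and susceptibilities in ppm.  The data residual is
`w · (f − d∗chi)`: the SNR weight multiplies the residual, not the field
alone.  Norms are plain sums over voxels (no per-voxel normalization); the
lambda values quoted throughout the package are defined under this
convention.

`d∗` is circular convolution with the k-space dipole kernel
`D(k) = 1/3 − (k·b̂₀)²/|k|²` evaluated on the DFT frequency lattice implied
by the grid dimensions and voxel size, with `D(0) := 0` — the mean
susceptibility is unobservable from internal field data, so reconstructions
are mean-free up to regularization.  `L` is the spherical-mean-value (SMV)
operator: normalized averaging over the voxels whose centers lie within
radius `k` of the target (voxel-center membership, so a 1 mm radius on a
1 mm isotropic grid is the 7-voxel center-plus-face-neighbors stencil).  A
radius below the smallest voxel dimension makes `L` the exact identity.
Gradients are forward differences with periodic wrap; the divergence is the
exact negative adjoint, so all adjoint identities used by the solver hold to
machine precision.

The adaptive mask is `r = exp(−|τ · (L R2*)|)`, computed with the same SMV
radius as the regularizer unless overridden.  It maps smoothed R2* (1/s)
through a decaying exponential: at the default τ = 0.05 s, cortical tissue at
R2* ≈ 20/s gets r ≈ 0.37 (moderate penalty), iron-rich nuclei at 40–50/s get
r ≈ 0.1, and signal-free regions whose R2* fit saturates in the hundreds get
r ≈ 0.  Outside the supplied head/brain mask r is set to its in-mask
minimum.  In practice that minimum is driven by the highest-R2* in-mask
tissue; when the mask contains signal-free structures (skull), the exterior
penalty becomes negligible, which is essential: air at 9 ppm must remain an
admissible part of the total-field solution, and penalizing it forces the
in-brain solution to absorb the background as a shadow bowl.

## Solver

The TV term is handled by iteratively reweighted least squares.  Each outer
iteration freezes weights `eta = 1/sqrt(|M_G grad chi|² + eps)` (eps = 1e-6
ppm²) and solves the normal equations

    (D^H W² D + lambda1 grad^T diag(M_G² eta) grad + 2 lambda2 L^H diag(r²) L) chi
        = D^H W² f

by conjugate gradients warm-started at the current iterate (relative
residual 1e-3, at most 150 iterations).  The IRLS update is accepted through
a backtracking line search that halves the step until the *exact* objective
does not increase, which turns the approximate monotonicity of inexact
IRLS/CG into a guarantee; if backtracking stalls and the objective still rose
by more than 1e-3 relative, the solver raises with the trace attached.  The
outer loop stops when the relative iterate change falls below 1e-3 or after
30 iterations.  Initialization is chi = 0; a warm start can be passed
explicitly.  These controls are engineering defaults (config-exposed), chosen
so the phantom reconstructions below converge deterministically in well under
their runtime budgets on one CPU.

Variants: `tfi_plain` forces lambda2 = 0 and shares every other code path
(bitwise-identical to `tfir` at lambda2 = 0).  `ln_qsm` replaces L by the
identity and r by the binary domain mask.  At τ = 0 and sub-voxel k, TFIR's
adaptive term degenerates to an unweighted least-norm penalty and coincides
with `ln_qsm` on a full-grid mask — the regime in which the two are compared
in the tests.  `medi_smv_linear` composes the data kernel with (I − SMV),
filters the field the same way, and restricts the weight to the SMV-eroded
mask (default 5 mm); it is a *linear* stand-in for SMV-filtered local-field
methods, kept as a comparator and not claimed to reproduce their nonlinear
signal model.

## Input fitting

R2* is fit voxelwise by log-linear least squares of magnitude versus echo
time, weighted by squared magnitude (near-ML at moderate SNR), clipped at 0.
The total field comes from a magnitude²-weighted linear fit of temporally
unwrapped phase versus echo time; successive-echo phase differences are
wrapped into (−π, π] and accumulated, which is exact while inter-echo
increments stay below π.  Spatial unwrapping is deliberately out of scope, so
echo times must be wrap-safe for the fields at hand; the simulator warns when
they are not.  The slope in rad/s is converted to ppm by dividing by
`2π · 42.576e6 · B0 · 1e-6`.  The noise weight w is the last-echo magnitude
(late-echo magnitude parallels the 1/r rationale of the adaptive mask; a
sum-of-squares alternative is available), normalized to unit mean in the
mask.

## Phantoms: what they emulate and what they do not

The brain phantom is an ellipsoidal head (0.48 of the field of view per
axis, so padded forward simulations stay aliasing-controlled) surrounded by
air at 9 ppm, with a −2 ppm skull shell, a smooth ±0.02 ppm tissue baseline,
6–10 spherical nuclei drawn in [−0.1, 0.3] ppm, a zero-susceptibility
ventricle, and an optional 1 ppm hemorrhage sphere (off by default).  R2* is
coupled monotonically to susceptibility over the whole head:
`R2* = 10 + 100·|chi − baseline|` 1/s.  That coupling encodes two physical
facts at once — iron-rich, high-|χ| tissue relaxes faster, and signal-free
structures (bone; by extension air) come out of any magnitude fit with very
large R2* — and it is what lets the adaptive mask release the penalty
exactly where susceptibility is large.  The gadolinium phantom is a
zero-susceptibility cylinder containing one sphere per concentration
({0.5, 1, 2, 3, 4} mM by default) at χ = 0.33 ppm/mM × c, with sphere R2* =
5 + 5·c 1/s and an external 9 ppm ellipsoid outside the mask to inject a
strong background field.  The shadow scenario adds to the clean total field
a spurious component synthesized from Fourier modes with integer index ≤ 2
per axis, scaled to 0.05 ppm RMS over the brain — a stand-in for residual
background/digitization error.  Echo times default to 1–8 ms at 3 T so that
temporal-only unwrapping stays exact for the multi-ppm total fields these
phantoms induce; this is shorter than clinical protocols and is a
consequence of omitting spatial unwrapping.

The phantoms deliberately omit realistic anatomy, coil combination, flow,
motion, fat, and chemical shift.  Passing tests therefore demonstrate the
correctness of the operators, the solver, and the qualitative shadow
behavior — not in vivo image quality.

Forward fields for simulation are computed with the dipole kernel on a
zero-padded (doubled) grid and cropped, which suppresses wraparound of the
strong air background; the solver itself uses the periodic kernel.  The
residual mismatch between the two is part of what the reconstruction has to
absorb, as in real data.

## Numerical and evaluation choices

* Reference reconstruction parameters follow the phantom optimization
  regime: λ₁ = 10⁻³, λ₂ = 0.025 (brain phantom) or 0.1 (Gd/shadow), τ =
  0.05 s, k = 1 mm, edge fraction 0.1.
* The 64³ brain phantom (seed 7) reconstructed at those parameters reaches
  ≤ 0.02 ppm in-brain RMSE; this is the reference accuracy check and runs in
  under a minute on one CPU.
* Edge masks use a per-axis in-mask quantile; ties at the threshold are
  classified as edges, except that a zero gradient is never an edge (a
  constant image has no edges).
* The shadow index is defined here as 1000 × the mean over the
  radius-eroded ROI of |SMV_radius applied to the ROI-restricted,
  mean-removed susceptibility|, in ppb (default radius 10 mm; 6 mm is used
  on the 48³ desk-scale phantoms so the eroded core stays well populated).
  It vanishes on constants, is nearly blind to voxel-scale texture, and
  grows monotonically with smooth bowls.  It is a package-defined statistic:
  its absolute values are not comparable to other implementations, only
  orderings between reconstructions of the same data are used.
* The binned susceptibility-vs-1/r analysis uses seven 0.05 ppm bins on
  [0, 0.35] ppm, per-bin medians of 1/r, and an OLS fit against bin centers;
  empty bins are dropped with a warning.
* Degenerate inputs fail loudly: empty masks, all-zero weights, non-finite
  volumes, grid mismatches (never broadcast), masks that vanish under
  erosion, and non-increasing echo times all raise.

## Known limitations

No spatial phase unwrapping, no preconditioning (convergence on strongly
ill-conditioned whole-head problems relies on regularization alone), linear
data model only, single fixed τ and k, and NIfTI volumes are taken in file
axis order without reorientation to RAS.  The mean susceptibility is not
recovered (D(0) = 0); comparisons of absolute values between
reconstructions should be referenced to a common region.
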