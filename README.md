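# qsmtfir

Adaptive total field inversion for quantitative susceptibility mapping (QSM).

## The problem

QSM reconstructs the magnetic susceptibility χ (ppm) of tissue from the field
perturbation measured with multi-echo gradient-echo MRI.  The measured *total*
field contains contributions from everything in the head — brain tissue
(−0.1 to 0.3 ppm), bone (≈ −2 ppm) and air (≈ 9 ppm) — and the dipole kernel
that links susceptibility to field has a conical null space, so a direct
inversion leaves smooth "shadow" bowls and streaking artifacts.  Conventional
pipelines first strip the background field and erode the brain mask;
total-field methods instead solve for the susceptibility of the entire field
of view at once, which avoids propagating background-removal errors but makes
shadow suppression harder.

`qsmtfir` implements a total field inversion with a spatially adaptive,
shadow-suppressing L2 regularizer (TFIR):

```
χ* = argmin_χ  ½‖w (f − d∗χ)‖₂² + λ₁ Σ‖M_G ∇χ‖₁ + λ₂ ‖r · (Lχ)‖₂²
```

where `f` is the total field (ppm), `d∗` the k-space dipole convolution
(`D(k) = 1/3 − (k·b̂₀)²/|k|²`), `w` the SNR weight, `M_G` a binary edge mask
that releases the strongest magnitude edges from the TV penalty, `L` a
spherical-mean-value (SMV) low-pass filter of radius `k`, and

```
r = exp(−|τ · L R2*|)
```

an adaptive mask built from the R2* map of the same acquisition.  Low-R2*
regions (presumed uniform) are penalized heavily against smooth susceptibility
variation; high-R2* structures (iron-rich nuclei, hemorrhage, signal-free bone
and air) are left essentially free.  The limiting cases are included: plain
TFI (λ₂ = 0), a least-norm-style variant (`ln_qsm`: L = identity, r = binary
mask) and a linear SMV-filtered comparator (`medi_smv_linear`).

The solver handles the TV term by IRLS with conjugate-gradient inner solves
and a backtracking safeguard, so the recorded objective trace is
non-increasing.

The package is synthetic-first: phantom generators (brain-like phantom with a
9 ppm air background, gadolinium sphere phantom at 0.33 ppm/mM, a
shadow-provoking scenario), a forward multi-echo GRE simulator, R2*/field
fitting, and evaluation metrics (RMSE, ROI statistics, regression slope,
shadow index, binned susceptibility-vs-1/r correlation) let the whole pipeline
run without scanner data.  Scanner-derived volumes can be supplied as NIfTI.

## Worked example

Reconstruct a shadow-contaminated 48³ brain phantom with TFIR and with plain
TFI, then score both:

```python
from qsmtfir import (PhantomSpec, TFIRParams, VoxelGrid, make_shadow_phantom,
                     prepare_inversion_inputs, reconstruct, rmse, shadow_index)

spec = PhantomSpec(grid=VoxelGrid((48, 48, 48), (1.25, 1.25, 1.25)), seed=1)
ph = make_shadow_phantom(spec)
params = TFIRParams(lambda1=1e-3, lambda2=0.1, tau_s=0.05, smv_radius_mm=1.0)
bundle = prepare_inversion_inputs(ph.chi_true, ph.r2star_true, ph.head_mask,
                                  params, field=ph.f_contaminated)
for variant in ("tfir", "tfi_plain"):
    p = TFIRParams(lambda1=1e-3, lambda2=0.1, tau_s=0.05, smv_radius_mm=1.0,
                   variant=variant)
    res = reconstruct(bundle["f"], bundle["w"], ph.head_mask,
                      bundle["mg_masks"], bundle["r"], p)
    err = rmse(res.chi, ph.chi_true, ph.brain_mask)
    si = shadow_index(res.chi, ph.brain_mask, radius_mm=6.0)
    print(f"{variant:10s}  in-brain RMSE = {err:.4f} ppm   shadow index = {si:.1f} ppb")
```

Output:

```
tfir        in-brain RMSE = 0.0423 ppm   shadow index = 8.8 ppb
tfi_plain   in-brain RMSE = 1.3639 ppm   shadow index = 74.8 ppb
```

The injected smooth field error (0.05 ppm RMS) passes almost untouched into
the plain-TFI susceptibility map as a shadow bowl (74.8 ppb); the adaptive L2
term suppresses it by roughly an order of magnitude while also cutting the
in-brain RMSE.

The same pipeline is available from the shell:

```
qsmtfir simulate --scenario brain --outdir sim/
qsmtfir recon --field f.nii.gz --weight w.nii.gz --mask m.nii.gz \
    --r2star r2s.nii.gz --lambda1 1e-3 --lambda2 0.1 --tau 0.05 --k-mm 1.0 \
    --variant tfir --out chi.nii.gz --log recon.json
qsmtfir metrics --chi chi.nii.gz --truth chi_true.nii.gz --mask m.nii.gz --out metrics.csv
```

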