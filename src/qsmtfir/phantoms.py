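"""Synthetic phantoms and forward GRE signal simulation.

All scanner data the method would normally consume are emulated here:

* a brain-like numerical phantom — ellipsoidal head surrounded by air at
  9 ppm, a -2 ppm skull shell, smooth tissue baseline with spherical
  "nuclei" in the -0.1..0.3 ppm tissue range, a zero-susceptibility
  ventricle, and an optional hemorrhage sphere — together with an R2* map
  coupled monotonically to the susceptibility deviation so that the
  adaptive mask sees what it would see in vivo;
* a gadolinium sphere phantom — a zero-susceptibility agarose cylinder with
  Gd-doped spheres at chi = 0.33 ppm/mM x concentration and an external
  high-susceptibility source injecting a strong background field;
* a shadow scenario — the brain phantom plus a strictly low-spatial-
  frequency spurious field added to the total field, emulating residual
  background/digitization error that produces shadow artifacts;
* a forward multi-echo GRE simulator with mono-exponential decay,
  field-induced phase evolution, and complex Gaussian noise.

Generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .operators import dipole_field
from .volumes import GAMMA_HZ_PER_T, MultiEchoGRE, ScalarVolume, VolumeError, VoxelGrid


@dataclass
class PhantomSpec:
    """Study conditions for the synthetic generators.

    Susceptibility values: 9 ppm air exterior, tissue in [-0.1, 0.3] ppm,
    skull at -2 ppm, hemorrhage 1 ppm, Gd relation 0.33 ppm/mM.  Echo times
    default to 1..8 ms so that temporal-only phase unwrapping remains exact
    for the multi-ppm total fields these phantoms induce.
    """

    grid: VoxelGrid = field(default_factory=lambda: VoxelGrid((64, 64, 64)))
    scenario: str = "brain"
    background_ppm: float = 9.0
    tissue_range_ppm: tuple[float, float] = (-0.1, 0.3)
    skull_ppm: float = -2.0
    hemorrhage_ppm: float = 1.0
    hemorrhage_radius_mm: float = 0.0  # 0 disables the hemorrhage sphere
    gd_concentrations_mM: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0)
    gd_slope_ppm_per_mM: float = 0.33
    gd_relaxivity_per_s_mM: float = 5.0
    noise_snr: float = np.inf
    te_s: tuple[float, ...] = (0.001, 0.002, 0.003, 0.004, 0.005, 0.006, 0.007, 0.008)
    b0_tesla: float = 3.0
    r2star_floor_per_s: float = 10.0
    r2star_per_ppm: float = 100.0
    shadow_rms_ppm: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.scenario == "brain" and min(self.grid.dims) < 32:
            raise VolumeError("brain scenario requires grid dims >= 32")
        if any(c < 0 for c in self.gd_concentrations_mM):
            raise VolumeError("Gd concentrations must be nonnegative")
        if not self.noise_snr > 0:
            raise VolumeError("noise_snr must be positive (np.inf for noiseless)")


@dataclass
class ShadowPhantom:
    """Brain phantom with a contaminated total field alongside the clean one."""

    chi_true: ScalarVolume
    r2star_true: ScalarVolume
    brain_mask: ScalarVolume
    head_mask: ScalarVolume
    f_clean: ScalarVolume
    f_contaminated: ScalarVolume
    injected_field: ScalarVolume


def _coords(grid: VoxelGrid):
    """Voxel-center coordinates in mm, origin at the grid center."""
    axes = [
        (np.arange(n) - n / 2.0 + 0.5) * v
        for n, v in zip(grid.dims, grid.voxel_size_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(coords, center_mm, semi_mm) -> np.ndarray:
    x, y, z = coords
    return (
        ((x - center_mm[0]) / semi_mm[0]) ** 2
        + ((y - center_mm[1]) / semi_mm[1]) ** 2
        + ((z - center_mm[2]) / semi_mm[2]) ** 2
    ) <= 1.0


def _smooth_field(rng, dims, sigma_vox=6.0) -> np.ndarray:
    """Unit-RMS smooth random field via Gaussian filtering of white noise."""
    g = ndimage.gaussian_filter(rng.standard_normal(dims), sigma=sigma_vox, mode="wrap")
    return g / max(g.std(), 1e-12)


def make_brain_phantom(spec: PhantomSpec):
    """Brain-like susceptibility/R2* phantom with a 9 ppm air exterior.

    Returns ``(chi_true, r2star_true, brain_mask, head_mask)``.  The head
    ellipsoid spans 0.48 of the field of view per axis so that padded
    forward simulations are aliasing-controlled.  In-brain non-hemorrhage
    susceptibility stays inside ``tissue_range_ppm``; R2* is the floor plus
    ``r2star_per_ppm`` times the absolute susceptibility deviation from the
    local baseline, making high-chi structures high-R2*.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    coords = _coords(grid)
    fov = grid.fov_mm
    head_semi = tuple(0.24 * f for f in fov)
    head = _ellipsoid(coords, (0.0, 0.0, 0.0), head_semi)
    skull_inner = _ellipsoid(coords, (0.0, 0.0, 0.0), tuple(0.92 * s for s in head_semi))
    brain = _ellipsoid(coords, (0.0, 0.0, 0.0), tuple(0.80 * s for s in head_semi))

    lo, hi = spec.tissue_range_ppm
    baseline = 0.02 * _smooth_field(rng, grid.dims)
    baseline = np.clip(baseline, lo + 0.02, hi - 0.02)

    chi = np.full(grid.dims, spec.background_ppm)
    chi[head] = 0.0
    chi[head & ~skull_inner] = spec.skull_ppm
    chi[brain] = baseline[brain]

    brain_semi_mm = min(head_semi) * 0.80
    n_nuclei = int(rng.integers(6, 11))
    for _ in range(n_nuclei):
        radius = rng.uniform(2.0, 4.0)
        # keep nucleus comfortably inside the brain
        c = rng.uniform(-0.6, 0.6, size=3) * brain_semi_mm
        sphere = (
            (coords[0] - c[0]) ** 2 + (coords[1] - c[1]) ** 2 + (coords[2] - c[2]) ** 2
        ) <= radius**2
        chi[sphere & brain] = rng.uniform(lo, hi)

    ventricle = _ellipsoid(
        coords,
        (0.0, 0.0, 0.0),
        (0.25 * brain_semi_mm, 0.15 * brain_semi_mm, 0.20 * brain_semi_mm),
    )
    chi[ventricle & brain] = 0.0

    hemorrhage = np.zeros(grid.dims, dtype=bool)
    if spec.hemorrhage_radius_mm > 0:
        c = (0.35 * brain_semi_mm, 0.0, 0.0)
        hemorrhage = (
            (coords[0] - c[0]) ** 2 + coords[1] ** 2 + coords[2] ** 2
        ) <= spec.hemorrhage_radius_mm**2
        if (hemorrhage & ~brain).any():
            raise VolumeError("hemorrhage sphere does not fit inside the brain mask")
        chi[hemorrhage] = spec.hemorrhage_ppm

    # monotone chi -> R2* coupling over the whole head: iron-rich nuclei,
    # hemorrhage and (signal-free) skull all read as high R2*, as an in vivo
    # R2* fit would report
    dev = np.abs(chi - baseline)
    r2s = np.zeros(grid.dims)
    r2s[head] = spec.r2star_floor_per_s + spec.r2star_per_ppm * dev[head]

    return (
        ScalarVolume(grid, chi, "susceptibility_ppm"),
        ScalarVolume(grid, r2s, "r2star_per_s"),
        ScalarVolume(grid, brain.astype(float), "mask"),
        ScalarVolume(grid, head.astype(float), "mask"),
    )


def make_gd_phantom(spec: PhantomSpec):
    """Gadolinium sphere phantom: chi = slope x concentration per sphere.

    Returns ``(chi_true, r2star_true, mask, sphere_labels)``.  The agarose
    cylinder has zero susceptibility; sphere R2* is a 5 s^-1 floor plus the
    Gd relaxivity times concentration; an external 9 ppm ellipsoid outside
    the mask injects a strong background field so the inversion is exercised
    in the total-field regime.
    """
    conc = list(spec.gd_concentrations_mM)
    if len(conc) < 3:
        raise VolumeError("need at least 3 Gd concentrations")
    grid = spec.grid
    coords = _coords(grid)
    fov = grid.fov_mm

    cyl_radius = 0.24 * min(fov[0], fov[1])
    cyl_half_h = 0.22 * fov[2]
    rho2 = coords[0] ** 2 + coords[1] ** 2
    cylinder = (rho2 <= cyl_radius**2) & (np.abs(coords[2]) <= cyl_half_h)

    chi = np.zeros(grid.dims)
    r2s = np.zeros(grid.dims)
    labels = np.zeros(grid.dims, dtype=np.int32)
    r2s[cylinder] = 5.0

    ring = 0.55 * cyl_radius
    angles = 2 * np.pi * np.arange(len(conc)) / len(conc)
    sphere_r = min(0.28 * cyl_radius, ring * np.sin(np.pi / len(conc)) * 0.9)
    centers = [(ring * np.cos(a), ring * np.sin(a), 0.0) for a in angles]
    for i, ((cx, cy, cz), c) in enumerate(zip(centers, conc), start=1):
        sph = (
            (coords[0] - cx) ** 2 + (coords[1] - cy) ** 2 + (coords[2] - cz) ** 2
        ) <= sphere_r**2
        if (labels[sph] != 0).any():
            raise VolumeError("Gd spheres overlap")
        if (sph & ~cylinder).any():
            raise VolumeError("Gd sphere extends outside the agarose cylinder")
        labels[sph] = i
        chi[sph] = spec.gd_slope_ppm_per_mM * c
        r2s[sph] = 5.0 + spec.gd_relaxivity_per_s_mM * c

    # external susceptibility source above the cylinder, outside the mask
    src_center = (0.0, 0.0, cyl_half_h + 0.18 * fov[2])
    src = _ellipsoid(coords, src_center, (0.15 * fov[0], 0.15 * fov[1], 0.08 * fov[2]))
    if (src & cylinder).any():
        raise VolumeError("external source intersects the phantom body")
    chi[src] = spec.background_ppm

    return (
        ScalarVolume(grid, chi, "susceptibility_ppm"),
        ScalarVolume(grid, r2s, "r2star_per_s"),
        ScalarVolume(grid, cylinder.astype(float), "mask"),
        ScalarVolume(grid, labels.astype(float), "generic"),
    )


def simulate_gre(
    chi_true: ScalarVolume,
    r2star_true: ScalarVolume,
    mask: ScalarVolume,
    spec: PhantomSpec,
) -> MultiEchoGRE:
    """Forward multi-echo GRE signal from a susceptibility/R2* phantom.

    ``S_j = M0 exp(-TE_j R2*) exp(i 2 pi f_Hz TE_j)`` with M0 = 1 inside the
    mask and the field from the zero-padded dipole convolution.  Complex
    Gaussian noise at ``spec.noise_snr`` (per-channel sigma = M0_peak /
    (snr sqrt(2))) is drawn from a stream derived from ``spec.seed``.  Warns
    if any in-mask inter-echo phase increment reaches pi (temporal
    unwrapping would alias).
    """
    grid = chi_true.grid
    grid.check_same(r2star_true.grid)
    grid.check_same(mask.grid)
    te = np.asarray(spec.te_s, dtype=float)

    field_ppm = dipole_field(chi_true, padded=True)
    f_hz = field_ppm.values * 1e-6 * GAMMA_HZ_PER_T * spec.b0_tesla
    dte = np.max(np.diff(te)) if te.size > 1 else te[0]
    max_step = 2 * np.pi * np.max(np.abs(f_hz[mask.values > 0])) * dte
    if max_step >= np.pi:
        warnings.warn(
            f"max in-mask inter-echo phase step {max_step:.2f} rad >= pi; "
            "temporal unwrapping will alias — choose shorter echo spacing",
            stacklevel=2,
        )

    m0 = mask.values
    echoes = np.empty((te.size,) + grid.dims, dtype=np.complex128)
    for j, t in enumerate(te):
        echoes[j] = (
            m0 * np.exp(-t * r2star_true.values) * np.exp(2j * np.pi * f_hz * t)
        )
    if np.isfinite(spec.noise_snr):
        rng = np.random.default_rng((spec.seed, 1))
        sigma = 1.0 / (spec.noise_snr * np.sqrt(2.0))
        echoes += sigma * (
            rng.standard_normal(echoes.shape) + 1j * rng.standard_normal(echoes.shape)
        )
    return MultiEchoGRE(grid, echoes, te)


def make_shadow_phantom(spec: PhantomSpec) -> ShadowPhantom:
    """Brain phantom whose total field carries a smooth spurious component.

    The injected field is synthesized from Fourier modes with integer
    frequency index at most 2 per axis (spectrally strictly below the SMV
    cutoff for any practical k), scaled to ``spec.shadow_rms_ppm`` RMS over
    the brain mask, and added globally to the clean total field.  With zero
    amplitude the output reduces exactly to the brain phantom path.
    """
    chi_true, r2s, brain, head = make_brain_phantom(spec)
    grid = spec.grid
    f_clean = dipole_field(chi_true, padded=True)

    if spec.shadow_rms_ppm == 0:
        injected = np.zeros(grid.dims)
    else:
        rng = np.random.default_rng((spec.seed, 2))
        spectrum = np.zeros(grid.dims, dtype=np.complex128)
        max_idx = 2
        for ix in range(-max_idx, max_idx + 1):
            for iy in range(-max_idx, max_idx + 1):
                for iz in range(-max_idx, max_idx + 1):
                    if ix == iy == iz == 0:
                        continue
                    amp = rng.standard_normal() + 1j * rng.standard_normal()
                    spectrum[ix, iy, iz] = amp / (ix**2 + iy**2 + iz**2)
        injected = np.real(np.fft.ifftn(spectrum))
        inb = brain.values > 0
        rms = np.sqrt(np.mean(injected[inb] ** 2))
        injected *= spec.shadow_rms_ppm / max(rms, 1e-30)

    f_cont = ScalarVolume(grid, f_clean.values + injected, "field_ppm")
    return ShadowPhantom(
        chi_true=chi_true,
        r2star_true=r2s,
        brain_mask=brain,
        head_mask=head,
        f_clean=f_clean,
        f_contaminated=f_cont,
        injected_field=ScalarVolume(grid, injected, "field_ppm"),
    )
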