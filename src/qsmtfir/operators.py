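"""Linear operators of the dipole inversion problem.

Three families of operators, all diagonal in the discrete frequency domain or
built from elementary finite differences:

* the k-space dipole kernel ``D(k) = 1/3 - (k.b0)^2 / |k|^2`` relating a
  susceptibility distribution (ppm) to the field perturbation it induces
  (ppm), with the unobservable mean fixed by ``D(0) = 0``;
* the spherical-mean-value (SMV) kernel, a normalized average over the voxels
  whose centers fall within a given radius — the low-pass filter ``L`` of the
  adaptive regularizer and the background-suppressing kernel of the
  SMV-filtered comparator;
* forward-difference gradient and its exact negative adjoint divergence under
  periodic boundary conditions.

Convolutions are circular (periodic) with no padding by default; the phantom
simulator uses :func:`dipole_field` with ``padded=True``, which zero-pads to
double size so that wraparound of the strong air background field is
controlled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from .volumes import ScalarVolume, VolumeError, VoxelGrid

KERNEL_KINDS = ("dipole", "smv", "smv_complement")


@dataclass
class KSpaceKernel:
    """A real symmetric frequency-domain multiplier on a voxel grid."""

    grid: VoxelGrid
    values: np.ndarray
    kernel_kind: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.dims:
            raise VolumeError("kernel shape does not match grid dims")
        if self.kernel_kind not in KERNEL_KINDS:
            raise VolumeError(f"unknown kernel kind {self.kernel_kind!r}")

    def half_spectrum(self) -> np.ndarray:
        """Kernel samples on the rfftn lattice (last axis truncated)."""
        nz = self.grid.dims[2]
        return self.values[..., : nz // 2 + 1]


@dataclass
class VectorVolume:
    """Per-axis partial differences of a scalar volume (ppm/voxel)."""

    grid: VoxelGrid
    components: tuple[np.ndarray, np.ndarray, np.ndarray]

    def __post_init__(self):
        comps = tuple(np.asarray(c, dtype=np.float64) for c in self.components)
        if len(comps) != 3 or any(c.shape != self.grid.dims for c in comps):
            raise VolumeError("component shapes must equal grid dims")
        self.components = comps


def _freq_lattice(grid: VoxelGrid):
    """Spatial frequencies (cycles/mm) of the DFT lattice, per axis."""
    return [
        np.fft.fftfreq(n, d=v)
        for n, v in zip(grid.dims, grid.voxel_size_mm)
    ]


def dipole_kernel(grid: VoxelGrid) -> KSpaceKernel:
    """Unit dipole response in k-space: ``1/3 - (k.b0)^2/|k|^2``, D(0) = 0.

    The zero-frequency value is set to 0 because the mean susceptibility is
    unobservable from internal field data (standard QSM convention);
    reconstructions are therefore mean-free up to regularization.
    """
    kx, ky, kz = _freq_lattice(grid)
    kx = kx[:, None, None]
    ky = ky[None, :, None]
    kz = kz[None, None, :]
    bx, by, bz = grid.b0_dir
    k2 = kx**2 + ky**2 + kz**2
    kb = kx * bx + ky * by + kz * bz
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 / 3.0 - kb**2 / k2
    d[0, 0, 0] = 0.0
    return KSpaceKernel(grid, d, "dipole")


def _sphere_footprint(dims, voxel_size_mm, radius_mm) -> np.ndarray:
    """Centered binary sphere by voxel-center membership, on the full grid."""
    axes = [
        (np.arange(n) - n // 2) * v for n, v in zip(dims, voxel_size_mm)
    ]
    x = axes[0][:, None, None]
    y = axes[1][None, :, None]
    z = axes[2][None, None, :]
    return (x**2 + y**2 + z**2) <= radius_mm**2 + 1e-12


def smv_kernel(grid: VoxelGrid, radius_mm: float) -> KSpaceKernel:
    """Frequency response of normalized averaging over a discrete sphere.

    The sphere is built by voxel-center membership (deterministic; radius
    1 mm on a 1 mm isotropic grid gives the 7-voxel kernel of center plus
    6-neighborhood).  The kernel has unit DC gain.  A radius smaller than the
    smallest voxel dimension yields the identity operator.
    """
    if radius_mm < 0:
        raise VolumeError("SMV radius must be nonnegative")
    if radius_mm < min(grid.voxel_size_mm):
        return KSpaceKernel(grid, np.ones(grid.dims), "smv")
    sphere = _sphere_footprint(grid.dims, grid.voxel_size_mm, radius_mm).astype(float)
    sphere /= sphere.sum()
    # sphere is centered at index n//2 per axis; shift its center to index 0
    spec = np.real(sfft.fftn(np.fft.ifftshift(sphere)))
    # symmetric real stencil -> real spectrum; clip fp dust outside [-1, 1]
    spec = np.clip(spec, -1.0, 1.0)
    return KSpaceKernel(grid, spec, "smv")


def smv_complement(kernel: KSpaceKernel) -> KSpaceKernel:
    """``I - SMV``: the high-pass complement used by the SMV comparator."""
    if kernel.kernel_kind != "smv":
        raise VolumeError("complement is defined for SMV kernels")
    return KSpaceKernel(kernel.grid, 1.0 - kernel.values, "smv_complement")


def apply_kspace(kernel: KSpaceKernel, vol: ScalarVolume) -> ScalarVolume:
    """Circular convolution via the frequency domain (linear, self-adjoint)."""
    kernel.grid.check_same(vol.grid)
    if kernel.kernel_kind == "smv" and np.all(kernel.values == 1.0):
        return ScalarVolume(vol.grid, vol.values.copy(), vol.kind)  # exact identity
    out = sfft.irfftn(
        kernel.half_spectrum() * sfft.rfftn(vol.values), s=vol.grid.dims
    )
    kind = "field_ppm" if kernel.kernel_kind == "dipole" else vol.kind
    if kind in ("mask", "r2star_per_s", "weight"):
        kind = "generic"
    return ScalarVolume(vol.grid, out, kind)


def gradient(vol: ScalarVolume) -> VectorVolume:
    """Forward finite differences per axis with periodic wrap."""
    v = vol.values
    comps = tuple(np.roll(v, -1, axis=a) - v for a in range(3))
    return VectorVolume(vol.grid, comps)


def divergence(vec: VectorVolume) -> ScalarVolume:
    """Discrete divergence; exact negative adjoint of :func:`gradient`."""
    out = np.zeros(vec.grid.dims)
    for a, c in enumerate(vec.components):
        out += c - np.roll(c, 1, axis=a)
    return ScalarVolume(vec.grid, out, "generic")


# array-level helpers used in solver hot loops (no dataclass wrapping)


def grad_arrays(v: np.ndarray):
    return [np.roll(v, -1, axis=a) - v for a in range(3)]


def grad_adjoint_arrays(comps) -> np.ndarray:
    """Adjoint of grad_arrays: sum_a (roll(c,+1,a) - c)."""
    out = np.zeros_like(comps[0])
    for a, c in enumerate(comps):
        out += np.roll(c, 1, axis=a) - c
    return out


def dipole_field(chi: ScalarVolume, padded: bool = True) -> ScalarVolume:
    """Field (ppm) induced by a susceptibility map (ppm).

    With ``padded=True`` the volume is zero-padded to double size before the
    circular convolution and the result cropped back, which suppresses
    wraparound contamination from strong sources (e.g. the 9 ppm air
    background of the brain phantom) — the regime the simulator needs.
    ``padded=False`` matches the periodic forward model the solver uses.
    """
    if not padded:
        return apply_kspace(dipole_kernel(chi.grid), chi)
    g = chi.grid
    big_dims = tuple(2 * n for n in g.dims)
    big = VoxelGrid(big_dims, g.voxel_size_mm, g.b0_dir)
    arr = np.zeros(big_dims)
    nx, ny, nz = g.dims
    arr[:nx, :ny, :nz] = chi.values
    kern = dipole_kernel(big)
    out = sfft.irfftn(kern.half_spectrum() * sfft.rfftn(arr), s=big_dims)
    return ScalarVolume(g, out[:nx, :ny, :nz], "field_ppm")
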