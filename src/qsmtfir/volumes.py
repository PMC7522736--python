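"""Volume/grid data model and NIfTI I/O shared by all other modules.

Conventions
-----------
* Array axis order is ``(x, y, z)`` with the NIfTI spatial axes taken in file
  order; no reorientation to RAS is attempted.  This is a synthetic-first tool
  and orientation handling is documented rather than silently applied.
* All field quantities are stored and processed in ppm.  Conversion to Hz
  happens only inside the GRE simulator and the phase-fitting routine.
* ``b0_dir`` (main-field direction) defaults to ``(0, 0, 1)`` and travels in a
  JSON sidecar, not the NIfTI header, which has no standard slot for it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

GAMMA_HZ_PER_T = 42.576e6
"""Proton gyromagnetic ratio over 2*pi, in Hz/T."""

#: physical kinds a ScalarVolume may declare
KINDS = ("field_ppm", "susceptibility_ppm", "r2star_per_s", "weight", "mask", "generic")

_MASK_TOL = 1e-6


class VolumeError(ValueError):
    """Raised on contract violations of the volume data model."""


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a 3D volume: dimensions, voxel size (mm), B0 direction.

    ``b0_dir`` is normalized to unit length at construction; a zero vector is
    rejected.
    """

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b0_dir: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        vox = tuple(float(v) for v in self.voxel_size_mm)
        if len(dims) != 3 or any(d < 4 for d in dims):
            raise VolumeError(f"grid dims must be a triple with all dims >= 4, got {dims}")
        if len(vox) != 3 or any(v <= 0 for v in vox):
            raise VolumeError(f"voxel sizes must be positive, got {vox}")
        b0 = np.asarray(self.b0_dir, dtype=float)
        nrm = float(np.linalg.norm(b0))
        if b0.shape != (3,) or nrm == 0.0:
            raise VolumeError(f"b0_dir must be a nonzero 3-vector, got {self.b0_dir}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size_mm", vox)
        object.__setattr__(self, "b0_dir", tuple(b0 / nrm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(d * v for d, v in zip(self.dims, self.voxel_size_mm))

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-9) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm, atol=atol)
            and np.allclose(self.b0_dir, other.b0_dir, atol=atol)
        )

    def check_same(self, other: "VoxelGrid") -> None:
        """Raise if two grids differ; binary operations never broadcast."""
        if not self.same_geometry(other):
            raise VolumeError(f"grid mismatch: {self} vs {other}")


def _validate_kind(values: np.ndarray, kind: str) -> np.ndarray:
    if kind not in KINDS:
        raise VolumeError(f"unknown volume kind {kind!r}; expected one of {KINDS}")
    if kind == "mask":
        rounded = np.rint(values)
        if np.max(np.abs(values - rounded)) > _MASK_TOL or not np.isin(
            rounded, (0.0, 1.0)
        ).all():
            raise VolumeError("mask volume contains values outside {0, 1}")
        return rounded
    if kind == "r2star_per_s" and np.any(values < 0):
        raise VolumeError("R2* volume contains negative values")
    if kind == "weight" and np.any(values < 0):
        raise VolumeError("weight volume contains negative values")
    return values


@dataclass
class ScalarVolume:
    """A 3D scalar field on a :class:`VoxelGrid` with a declared physical kind."""

    grid: VoxelGrid
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.shape != self.grid.dims:
            raise VolumeError(
                f"values shape {vals.shape} does not match grid dims {self.grid.dims}"
            )
        self.values = _validate_kind(vals, self.kind)

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "ScalarVolume":
        """New volume on the same grid (kind inherited unless overridden)."""
        return ScalarVolume(self.grid, values, self.kind if kind is None else kind)


@dataclass
class MultiEchoGRE:
    """Per-echo complex 3D gradient-echo images plus echo times in seconds."""

    grid: VoxelGrid
    echoes: np.ndarray  # complex, shape (n_echo, nx, ny, nz)
    te_s: np.ndarray  # strictly increasing positive echo times

    def __post_init__(self):
        self.echoes = np.asarray(self.echoes, dtype=np.complex128)
        self.te_s = np.asarray(self.te_s, dtype=np.float64)
        if self.echoes.ndim != 4 or self.echoes.shape[1:] != self.grid.dims:
            raise VolumeError(
                f"echoes must have shape (n_echo, *dims), got {self.echoes.shape}"
            )
        if self.echoes.shape[0] < 2 or self.te_s.shape != (self.echoes.shape[0],):
            raise VolumeError("need >= 2 echoes with one echo time each")
        if np.any(self.te_s <= 0) or np.any(np.diff(self.te_s) <= 0):
            raise VolumeError("echo times must be positive and strictly increasing")

    @property
    def n_echoes(self) -> int:
        return self.echoes.shape[0]


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path, expected_kind: str = "generic", b0_dir=(0.0, 0.0, 1.0)) -> ScalarVolume:
    """Read a 3D NIfTI volume, populating the grid from header voxel sizes.

    ``expected_kind`` is validated against the voxel data (masks must be 0/1
    within 1e-6, R2* and weights nonnegative).  A non-3D file raises.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise VolumeError(f"{path}: expected a 3D volume, got {data.ndim} dimensions")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    grid = VoxelGrid(data.shape, zooms, b0_dir)
    return ScalarVolume(grid, np.asarray(data, dtype=np.float64), expected_kind)


def write_volume(vol: ScalarVolume, path) -> Path:
    """Write a volume as NIfTI; float32 voxel data (uint8 for masks).

    The header carries ``voxel_size_mm`` through a diagonal affine.
    """
    path = Path(path)
    affine = np.diag(list(vol.grid.voxel_size_mm) + [1.0])
    if vol.kind == "mask":
        data = vol.values.astype(np.uint8)
    else:
        data = vol.values.astype(np.float32)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.grid.voxel_size_mm)
    try:
        nib.save(img, str(path))
    except OSError as exc:  # unwritable path
        raise OSError(f"cannot write volume to {path}: {exc}") from exc
    if not path.exists():
        raise OSError(f"cannot write volume to {path}")
    return path


def write_sidecar(path, te_s=None, b0_tesla: float = 3.0, b0_dir=(0.0, 0.0, 1.0)) -> Path:
    """Write the JSON sidecar holding echo times, B0 strength and direction."""
    path = Path(path)
    payload = {
        "te_s": None if te_s is None else [float(t) for t in np.asarray(te_s).ravel()],
        "b0_tesla": float(b0_tesla),
        "b0_dir": [float(c) for c in b0_dir],
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_sidecar(path) -> dict:
    payload = json.loads(Path(path).read_text())
    if "b0_dir" in payload:
        payload["b0_dir"] = tuple(payload["b0_dir"])
    return payload
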