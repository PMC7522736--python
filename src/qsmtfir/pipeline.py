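"""Convenience assembly of solver inputs from phantom ground truth.

Bundles the repeated evaluation recipe: noiseless total field by padded
dipole convolution, uniform in-mask data weight, TV edge masks from a
synthetic late-echo magnitude ``mask * exp(-te_proxy * R2*)``, and the
adaptive mask r built with the regularizer's own SMV radius.
"""

from __future__ import annotations

import numpy as np

from .masks import edge_mask, weight_mask_r
from .operators import dipole_field, smv_kernel
from .solver import TFIRParams
from .volumes import ScalarVolume


def prepare_inversion_inputs(
    chi_true: ScalarVolume,
    r2star: ScalarVolume,
    mask: ScalarVolume,
    params: TFIRParams,
    te_proxy_s: float = 0.01,
    field: ScalarVolume | None = None,
) -> dict:
    """Solver inputs for a known-truth phantom (noiseless by default).

    ``field`` overrides the padded forward simulation (e.g. a contaminated
    field from the shadow scenario).  Returns a dict with keys ``f``, ``w``,
    ``mask``, ``mg_masks``, ``r``, ``r2star`` — the bundle
    :func:`qsmtfir.solver.grid_search` consumes.
    """
    grid = chi_true.grid
    f = field if field is not None else dipole_field(chi_true, padded=True)
    w = ScalarVolume(grid, mask.values, "weight")
    magnitude = ScalarVolume(
        grid, mask.values * np.exp(-te_proxy_s * r2star.values), "generic"
    )
    mg = edge_mask(magnitude, mask, params.edge_fraction)
    L = smv_kernel(grid, max(params.smv_radius_mm, min(grid.voxel_size_mm)))
    r = weight_mask_r(r2star, params.tau_s, L, mask)
    return {"f": f, "w": w, "mask": mask, "mg_masks": mg, "r": r, "r2star": r2star}
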