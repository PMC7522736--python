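"""Spatial weightings of the regularized total field inversion.

* ``edge_mask`` builds the binary gradient mask M_G gating the TV penalty:
  the strongest magnitude edges (a configurable fraction, default 10%) are
  left unpenalized so susceptibility discontinuities that coincide with
  anatomy survive the reconstruction.
* ``weight_mask_r`` builds the adaptive shadow-suppression mask
  ``r = exp(-|tau * (L R2*)|)``: low-R2* (presumed uniform) tissue is
  penalized heavily by the L2 term, high-R2* structures barely at all.
"""

from __future__ import annotations

import numpy as np

from .operators import KSpaceKernel, apply_kspace
from .volumes import ScalarVolume, VolumeError


def edge_mask(
    magnitude: ScalarVolume, mask: ScalarVolume, edge_fraction: float = 0.1
) -> tuple[ScalarVolume, ScalarVolume, ScalarVolume]:
    """Per-axis binary masks that are 0 on the strongest magnitude edges.

    For each axis the absolute forward difference of the magnitude is
    computed; inside the mask, the ``edge_fraction`` of voxels with the
    largest differences receive M_G = 0 (edges, unpenalized by TV) and all
    others 1.  The threshold is the per-axis in-mask (1 - edge_fraction)
    quantile; ties at the threshold are all classified as edges, except that
    a zero gradient is never an edge (so a constant image yields all-ones
    masks).
    """
    magnitude.grid.check_same(mask.grid)
    if not 0.0 <= edge_fraction <= 1.0:
        raise VolumeError("edge_fraction must lie in [0, 1]")
    inmask = mask.values > 0
    n = int(inmask.sum())
    if n == 0:
        raise VolumeError("empty mask")
    out = []
    for axis in range(3):
        g = np.abs(np.roll(magnitude.values, -1, axis=axis) - magnitude.values)
        vals = np.sort(g[inmask])
        if edge_fraction == 0.0:
            thr = np.inf
        else:
            # order statistic such that >= edge_fraction of in-mask voxels
            # satisfy g >= thr (ties push the edge count up, never down)
            idx = min(int(np.floor((1.0 - edge_fraction) * n)), n - 1)
            thr = vals[idx]
        edges = inmask & (g >= thr) & (g > 0)
        out.append(ScalarVolume(magnitude.grid, (~edges).astype(float), "mask"))
    return tuple(out)


def weight_mask_r(
    r2star: ScalarVolume,
    tau_s: float,
    L: KSpaceKernel,
    mask: ScalarVolume | None = None,
) -> ScalarVolume:
    """Adaptive regularization mask ``r = exp(-|tau * (L R2*)|)``.

    ``L`` must be an SMV kernel (by default the solver shares the radius k of
    its regularizer).  Values lie in (0, 1]; tau = 0 gives r = 1 everywhere,
    degenerating the adaptive term to an unweighted least-norm penalty.  When
    a head/brain ``mask`` is supplied, voxels outside it are set to the
    in-mask minimum rather than 1, so the L2 term never dominates exterior
    voxels in whole-head use.
    """
    if L.kernel_kind != "smv":
        raise VolumeError("weight mask requires an SMV low-pass kernel")
    if tau_s < 0:
        raise VolumeError("tau must be nonnegative")
    L.grid.check_same(r2star.grid)
    smoothed = apply_kspace(L, r2star).values
    r = np.exp(-np.abs(tau_s * smoothed))
    if mask is not None:
        mask.grid.check_same(r2star.grid)
        inmask = mask.values > 0
        if not inmask.any():
            raise VolumeError("empty mask")
        r = np.where(inmask, r, r[inmask].min())
    return ScalarVolume(r2star.grid, r, "weight")
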