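"""Quantitative evaluation of susceptibility reconstructions.

Includes the shadow index: because shadow artifacts are smooth error bowls,
the index low-pass filters the ROI-mean-removed susceptibility with an SMV
kernel (default radius 10 mm) and averages its magnitude over the
radius-eroded ROI, reported in ppb.  It is zero for constants, nearly blind
to high-frequency texture, and monotone in the amplitude of smooth bowls.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .operators import _sphere_footprint, apply_kspace, smv_kernel
from .volumes import ScalarVolume, VolumeError


def rmse(chi: ScalarVolume, truth: ScalarVolume, mask: ScalarVolume) -> float:
    """Root mean squared difference (ppm) over the mask voxels."""
    chi.grid.check_same(truth.grid)
    chi.grid.check_same(mask.grid)
    m = mask.values > 0
    if not m.any():
        raise VolumeError("empty mask")
    diff = chi.values[m] - truth.values[m]
    return float(np.sqrt(np.mean(diff**2)))


def roi_stats(chi: ScalarVolume, labels: ScalarVolume) -> pd.DataFrame:
    """Per-label (mean, std, std/mean, n) table; label 0 is background.

    Standard deviations are population (ddof=0) so single-voxel and constant
    regions report 0 rather than NaN.
    """
    chi.grid.check_same(labels.grid)
    lab = np.rint(labels.values).astype(int)
    if np.any(lab < 0):
        raise VolumeError("labels must be nonnegative integers")
    ids = np.unique(lab)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise VolumeError("no nonzero labels")
    rows = []
    for i in ids:
        vals = chi.values[lab == i]
        mean = float(vals.mean())
        std = float(vals.std(ddof=0))
        rows.append(
            {
                "label": int(i),
                "mean": mean,
                "std": std,
                "std_over_mean": std / mean if mean != 0 else np.nan,
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def regression_slope(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, r^2)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or np.unique(x).size < 2:
        raise VolumeError("need at least 2 distinct x values")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def shadow_index(chi: ScalarVolume, roi_mask: ScalarVolume, radius_mm: float = 10.0) -> float:
    """Smooth-artifact index in ppb over an ROI.

    ``SI = 1000 x mean over the radius-eroded ROI of |SMV_radius(m (chi -
    mean_ROI chi))|`` where m is the ROI indicator: the deviation is
    support-restricted to the ROI so susceptibility outside it (e.g. air)
    cannot leak into the average.  Invariant to adding a global constant.
    """
    chi.grid.check_same(roi_mask.grid)
    m = roi_mask.values > 0
    if not m.any():
        raise VolumeError("empty ROI mask")
    box = tuple(
        2 * int(np.floor(radius_mm / v)) + 1 for v in chi.grid.voxel_size_mm
    )
    footprint = _sphere_footprint(box, chi.grid.voxel_size_mm, radius_mm)
    core = ndimage.binary_erosion(m, structure=footprint)
    if not core.any():
        raise VolumeError("ROI vanishes after erosion; reduce radius_mm")
    dev = np.where(m, chi.values - chi.values[m].mean(), 0.0)
    smooth = apply_kspace(
        smv_kernel(chi.grid, radius_mm), ScalarVolume(chi.grid, dev, "generic")
    ).values
    return float(1000.0 * np.mean(np.abs(smooth[core])))


def binned_inverse_r_correlation(
    chi: ScalarVolume,
    r: ScalarVolume,
    bin_width_ppm: float = 0.05,
    range_ppm: tuple[float, float] = (0.0, 0.35),
    mask: ScalarVolume | None = None,
):
    """Binned correlation between susceptibility and 1/r.

    Susceptibility values are binned (default: seven 0.05 ppm bins spanning
    [0, 0.35] ppm); per bin the median of 1/r is taken and an OLS regression
    of median(1/r) on the bin-center susceptibility is returned as
    ``(table, slope, r2)``.  Empty bins are dropped with a warning.
    """
    chi.grid.check_same(r.grid)
    lo, hi = range_ppm
    edges = np.arange(lo, hi + 0.5 * bin_width_ppm, bin_width_ppm)
    sel = np.ones(chi.grid.dims, dtype=bool)
    if mask is not None:
        chi.grid.check_same(mask.grid)
        sel = mask.values > 0
    cv = chi.values[sel]
    inv_r = 1.0 / r.values[sel]
    rows = []
    for b in range(len(edges) - 1):
        in_bin = (cv >= edges[b]) & (
            cv <= edges[b + 1] if b == len(edges) - 2 else cv < edges[b + 1]
        )
        center = 0.5 * (edges[b] + edges[b + 1])
        if not in_bin.any():
            warnings.warn(f"empty susceptibility bin at {center:.3f} ppm; dropped",
                          stacklevel=2)
            continue
        rows.append(
            {
                "bin_center_ppm": center,
                "median_inv_r": float(np.median(inv_r[in_bin])),
                "n": int(in_bin.sum()),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 2:
        raise VolumeError("fewer than 2 nonempty bins; cannot regress")
    slope, _, r2 = regression_slope(table["bin_center_ppm"], table["median_inv_r"])
    return table, slope, r2
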