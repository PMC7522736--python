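"""Estimation of the solver inputs from multi-echo gradient-echo data.

Produces the total field ``f`` (ppm), the SNR weight ``w`` (unit mean inside
the mask), and the R2* map (1/s) that drives the adaptive regularization
mask.  Phase is unwrapped temporally only: successive-echo phase differences
are wrapped into (-pi, pi] and accumulated, which is exact whenever the
inter-echo phase increment stays below pi in magnitude.  Echo times must be
chosen wrap-safe accordingly (|2 pi f_Hz dTE| < pi); spatial unwrapping is
out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volumes import GAMMA_HZ_PER_T, MultiEchoGRE, ScalarVolume, VolumeError


@dataclass
class FitResult:
    """Outputs of the multi-echo fit feeding the dipole inversion."""

    field_ppm: ScalarVolume
    r2star: ScalarVolume
    m0: ScalarVolume
    weight: ScalarVolume


def _wls_slope_intercept(t: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Voxelwise weighted least squares of y against t along axis 0.

    t has shape (n,), y and w shape (n, ...).  Returns (slope, intercept)
    with zero where the weighted design is degenerate.
    """
    t = t.reshape((-1,) + (1,) * (y.ndim - 1))
    sw = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tbar = (w * t).sum(axis=0) / sw
        ybar = (w * y).sum(axis=0) / sw
        stt = (w * (t - tbar) ** 2).sum(axis=0)
        sty = (w * (t - tbar) * (y - ybar)).sum(axis=0)
        slope = sty / stt
        intercept = ybar - slope * tbar
    bad = ~np.isfinite(slope)
    slope = np.where(bad, 0.0, slope)
    intercept = np.where(bad | ~np.isfinite(intercept), 0.0, intercept)
    return slope, intercept


def fit_r2star(data: MultiEchoGRE, mask: ScalarVolume) -> ScalarVolume:
    """Mono-exponential decay rate from magnitude vs echo time.

    Log-linear least squares weighted by squared magnitude (near-ML for
    Gaussian noise at moderate SNR, closed form).  Negative estimates are
    clipped to 0; voxels outside the mask, or with any zero-magnitude echo,
    are set to 0.
    """
    data.grid.check_same(mask.grid)
    mag = np.abs(data.echoes)
    m = mask.values > 0
    zero = (mag <= 0).any(axis=0)
    if (zero & m).any():
        warnings.warn(
            f"{int((zero & m).sum())} in-mask voxels have a zero-magnitude echo; "
            "excluded from the R2* fit",
            stacklevel=2,
        )
    valid = m & ~zero
    logm = np.where(mag > 0, np.log(np.where(mag > 0, mag, 1.0)), 0.0)
    slope, _ = _wls_slope_intercept(data.te_s, logm, mag**2)
    r2s = np.clip(-slope, 0.0, None)
    r2s[~valid] = 0.0
    return ScalarVolume(data.grid, r2s, "r2star_per_s")


def _temporal_unwrap(echoes: np.ndarray) -> np.ndarray:
    """Accumulated phase per echo from wrapped successive differences."""
    phase = np.empty(echoes.shape)
    phase[0] = np.angle(echoes[0])
    increments = np.angle(echoes[1:] * np.conj(echoes[:-1]))
    phase[1:] = phase[0] + np.cumsum(increments, axis=0)
    return phase


def noise_weight(magnitude: ScalarVolume, mask: ScalarVolume) -> ScalarVolume:
    """SNR weight proportional to magnitude inside the mask, mean 1 in mask."""
    magnitude.grid.check_same(mask.grid)
    m = mask.values > 0
    if not m.any():
        raise VolumeError("empty mask")
    w = np.where(m, magnitude.values, 0.0)
    mean = w[m].mean()
    if mean <= 0:
        raise VolumeError("magnitude is zero everywhere inside the mask")
    return ScalarVolume(magnitude.grid, w / mean, "weight")


def fit_total_field(
    data: MultiEchoGRE,
    mask: ScalarVolume,
    b0_tesla: float,
    use_sos_magnitude: bool = False,
) -> FitResult:
    """Total field in ppm from the phase evolution across echoes.

    Per-voxel phase slope versus TE by magnitude^2-weighted linear fit after
    temporal unwrapping; the slope (rad/s) is converted to ppm by dividing by
    ``2 pi * gamma_bar * B0 * 1e-6``.  The weight volume is the last-echo
    magnitude (or sum-of-squares magnitude when ``use_sos_magnitude``)
    normalized to unit mean inside the mask — late-echo magnitude tracks the
    1/r rationale of the adaptive regularizer.
    """
    if b0_tesla <= 0:
        raise VolumeError("b0_tesla must be positive")
    data.grid.check_same(mask.grid)
    mag = np.abs(data.echoes)
    phase = _temporal_unwrap(data.echoes)
    slope_rad_s, _ = _wls_slope_intercept(data.te_s, phase, mag**2)
    field = slope_rad_s / (2 * np.pi * GAMMA_HZ_PER_T * b0_tesla * 1e-6)
    field = np.where(mask.values > 0, field, 0.0)

    r2s = fit_r2star(data, mask)
    log_slope, log_icpt = _wls_slope_intercept(
        data.te_s, np.where(mag > 0, np.log(np.where(mag > 0, mag, 1.0)), 0.0), mag**2
    )
    m0 = np.where(mask.values > 0, np.exp(log_icpt), 0.0)

    wmag = np.sqrt((mag**2).sum(axis=0)) if use_sos_magnitude else mag[-1]
    weight = noise_weight(ScalarVolume(data.grid, wmag, "generic"), mask)
    return FitResult(
        field_ppm=ScalarVolume(data.grid, field, "field_ppm"),
        r2star=r2s,
        m0=ScalarVolume(data.grid, m0, "generic"),
        weight=weight,
    )
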