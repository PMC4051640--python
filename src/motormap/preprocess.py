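"""Resting-state denoising chain and shared smoothing / tSNR utilities.

The resting-state chain runs in a fixed order:

    confound regression -> polynomial detrend -> low-pass filter
        -> global signal regression -> spatial smoothing

Each step is a pure function on a :class:`~motormap.images.BoldSeries`;
:func:`preprocess_rest` asserts the order. Task runs reuse only the
smoothing step (applied to the series before the GLM).

Numerical notes
---------------
* Polynomial detrending uses an orthonormalized Legendre-style basis on
  a [-1, 1] time axis, so high orders stay well conditioned; the result
  is basis-invariant (it is the least-squares projection).
* The low-pass filter is zero-phase frequency-domain apodization: unit
  gain below the cutoff, raised-cosine roll-off of width 0.02 Hz centred
  on the cutoff, zero above. Zero phase keeps centre-of-mass and overlap
  measures comparable between filtered and unfiltered maps.
* Global signal regression is single-pass OLS of each voxel on the
  brain-mean time course (plus intercept); the residual mean course is
  analytically zero.
* Smoothing is volume-wise 3D Gaussian convolution with zero padding,
  sigma = FWHM / (2 sqrt(2 ln 2)) per axis expressed in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .images import BoldSeries, RoiMask, require_same_grid

__all__ = [
    "PreprocessConfig",
    "regress_confounds",
    "detrend_polynomial",
    "lowpass_filter",
    "global_signal_regress",
    "gaussian_smooth",
    "temporal_snr",
    "preprocess_rest",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
ROLLOFF_WIDTH_HZ = 0.02


@dataclass
class PreprocessConfig:
    """Parameters of the resting-state chain (defaults follow clinical practice
    for low-frequency connectivity mapping: cubic detrend, 0.1 Hz low pass,
    8 mm smoothing, global signal regression on)."""

    poly_order: int = 3
    lowpass_hz: float = 0.1
    fwhm_mm: float = 8.0
    do_gsr: bool = True
    confounds: np.ndarray | None = None

    def validate(self, tr: float) -> None:
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")
        nyquist = 1.0 / (2.0 * tr)
        if not 0 < self.lowpass_hz < nyquist:
            raise ValueError(
                f"lowpass_hz must be in (0, {nyquist:.4g}) for TR {tr}"
            )
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")


def _residualize(data2d: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residual of each row of ``data2d`` against ``design``
    columns. Falls back to the pseudo-inverse (with a warning) when the
    design is rank deficient."""
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient confound design; using pseudo-inverse")
    beta = np.linalg.pinv(design) @ data2d.T
    return data2d - (design @ beta).T


def regress_confounds(series: BoldSeries, confounds: np.ndarray) -> BoldSeries:
    """Remove nuisance time courses (e.g. motion parameters) by OLS.

    Each voxel course is replaced by its residual against
    ``[intercept | confounds]``; residuals are orthogonal to every
    confound column.
    """
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != series.n_volumes:
        if confounds.shape[1] == series.n_volumes:
            confounds = confounds.T
        else:
            raise ValueError(
                f"confounds have {confounds.shape[0]} rows, series has "
                f"{series.n_volumes} volumes"
            )
    design = np.column_stack([np.ones(series.n_volumes), confounds])
    flat = series.data.reshape(-1, series.n_volumes)
    return series.with_data(_residualize(flat, design).reshape(series.data.shape))


def _poly_basis(n: int, order: int) -> np.ndarray:
    """Orthonormal polynomial basis (constant..order) on n time points."""
    tau = np.linspace(-1.0, 1.0, n)
    cols = [tau**k for k in range(order + 1)]
    q, _ = np.linalg.qr(np.column_stack(cols))
    return q


def detrend_polynomial(series: BoldSeries, order: int = 3) -> BoldSeries:
    """Subtract the per-voxel least-squares polynomial baseline."""
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    if series.n_volumes <= order + 1:
        raise ValueError(
            f"need more than {order + 1} volumes for an order-{order} detrend"
        )
    basis = _poly_basis(series.n_volumes, order)
    flat = series.data.reshape(-1, series.n_volumes)
    fitted = (flat @ basis) @ basis.T  # orthonormal basis: projection is B B'
    return series.with_data((flat - fitted).reshape(series.data.shape))


def _lowpass_gain(freqs: np.ndarray, cutoff_hz: float,
                  width_hz: float = ROLLOFF_WIDTH_HZ) -> np.ndarray:
    lo, hi = cutoff_hz - width_hz / 2.0, cutoff_hz + width_hz / 2.0
    gain = np.ones_like(freqs)
    ramp = (freqs > lo) & (freqs < hi)
    gain[ramp] = 0.5 * (1.0 + np.cos(np.pi * (freqs[ramp] - lo) / (hi - lo)))
    gain[freqs >= hi] = 0.0
    return gain


def lowpass_filter(series: BoldSeries, cutoff_hz: float = 0.1) -> BoldSeries:
    """Zero-phase low-pass via frequency-domain apodization (see module
    docstring). Pass band (<= 0.5 x cutoff) is retained at >= 0.95 amplitude,
    stop band (>= 2 x cutoff) attenuated to <= 0.05."""
    nyquist = 1.0 / (2.0 * series.tr)
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz not below Nyquist {nyquist:.4g} Hz")
    n = series.n_volumes
    freqs = np.fft.rfftfreq(n, d=series.tr)
    gain = _lowpass_gain(freqs, cutoff_hz)
    flat = series.data.reshape(-1, n)
    spec = np.fft.rfft(flat, axis=1) * gain[None, :]
    return series.with_data(np.fft.irfft(spec, n, axis=1).reshape(series.data.shape))


def global_signal_regress(series: BoldSeries, brain_mask: RoiMask) -> BoldSeries:
    """Regress the brain-average time course out of every voxel (single-pass OLS)."""
    require_same_grid(series, brain_mask, "series and brain mask")
    if brain_mask.is_empty:
        raise ValueError("brain mask is empty")
    g = series.data[brain_mask.values].mean(axis=0)
    if g.std() == 0:
        # constant global signal: intercept alone removes it
        g = g + 0.0
    design = np.column_stack([np.ones(series.n_volumes), g])
    flat = series.data.reshape(-1, series.n_volumes)
    return series.with_data(_residualize(flat, design).reshape(series.data.shape))


def gaussian_smooth(data: np.ndarray | BoldSeries, fwhm_mm: float,
                    voxel_size_mm: np.ndarray | float | None = None):
    """Volume-wise isotropic Gaussian smoothing (zero-padded edges).

    Accepts a 3D array, a 4D array (smoothed per volume) or a
    :class:`BoldSeries` (voxel size taken from its affine).
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if isinstance(data, BoldSeries):
        vox = np.abs(np.diag(data.affine[:3, :3]))
        out = gaussian_smooth(data.data, fwhm_mm, vox)
        return data.with_data(out)
    arr = np.asarray(data, dtype=float)
    if fwhm_mm == 0:
        return arr.copy()
    if voxel_size_mm is None:
        raise ValueError("voxel_size_mm required when smoothing a bare array")
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vox
    if arr.ndim == 3:
        return ndimage.gaussian_filter(arr, sigma_vox, mode="constant")
    if arr.ndim == 4:
        out = np.empty_like(arr)
        for t in range(arr.shape[3]):
            out[..., t] = ndimage.gaussian_filter(arr[..., t], sigma_vox,
                                                  mode="constant")
        return out
    raise ValueError("expected a 3D or 4D array")


def temporal_snr(series: BoldSeries, mask: RoiMask) -> float:
    """Mean over mask voxels of (temporal mean / temporal SD).

    Zero-variance voxels are excluded with a warning.
    """
    require_same_grid(series, mask, "series and mask")
    if mask.is_empty:
        raise ValueError("mask is empty")
    courses = series.data[mask.values]
    mean = courses.mean(axis=1)
    sd = courses.std(axis=1, ddof=0)
    ok = sd > 0
    if not ok.any():
        raise ValueError("all mask voxels have zero temporal variance")
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} zero-variance voxels from tSNR")
    return float(np.mean(mean[ok] / sd[ok]))


def preprocess_rest(series: BoldSeries, brain_mask: RoiMask,
                    config: PreprocessConfig | None = None) -> BoldSeries:
    """Full resting-state chain in the fixed order
    confounds -> detrend -> low-pass -> GSR -> smoothing."""
    config = config or PreprocessConfig()
    config.validate(series.tr)
    out = series
    if config.confounds is not None:
        out = regress_confounds(out, config.confounds)
    out = detrend_polynomial(out, config.poly_order)
    out = lowpass_filter(out, config.lowpass_hz)
    if config.do_gsr:
        out = global_signal_regress(out, brain_mask)
    out = gaussian_smooth(out, config.fwhm_mm)
    return out
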