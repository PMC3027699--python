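"""Time-series conditioning: nuisance regression, normalization, smoothing,
band-pass.

The conditioning chain applied before connectivity analysis is
spatial smoothing -> temporal normalization -> nuisance (motion)
regression -> band-pass filtering of the residuals at 0.01-0.08 Hz.
The band-pass is a discrete-Fourier hard cutoff (zero every bin outside
the passband, including DC), which is exactly linear, phase-free and
testable bin by bin.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .structures import BoldSeries, NuisanceDesign, voxel_sizes

logger = logging.getLogger("dmnconnect.preprocess")

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


def regress_nuisance(series: BoldSeries, design: NuisanceDesign) -> BoldSeries:
    """Residualize each masked voxel's series on [intercept | regressors].

    Out-of-mask voxels are zeroed.  A rank-deficient design raises,
    naming the collinear columns.
    """
    X = design.with_intercept()
    t, k1 = X.shape
    if t != series.n_frames:
        raise ValueError(
            f"design has {t} rows but series has {series.n_frames} frames")
    if k1 >= t:
        raise ValueError(f"{k1 - 1} regressors + intercept >= {t} frames")
    rank = np.linalg.matrix_rank(X)
    if rank < k1:
        # identify columns whose removal restores full rank
        bad = []
        for j in range(1, k1):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(design.names[j - 1])
        raise ValueError(
            f"nuisance design is rank-deficient (rank {rank} < {k1}); "
            f"collinear columns: {bad or 'intercept-related'}")

    q, _ = np.linalg.qr(X)
    y = series.masked()                      # (t, V)
    q = q.astype(y.dtype, copy=False)
    resid = y - q @ (q.T @ y)
    out = np.zeros_like(series.data, dtype=resid.dtype)
    out[series.mask] = resid.T
    return series.with_data(out)


def temporal_normalize(series: BoldSeries, mode: str = "zscore",
                       eps: float = 1e-12) -> BoldSeries:
    """Per-voxel temporal standardization inside the mask.

    ``zscore`` (default): mean 0, sample SD 1.  ``psc``: percent signal
    change about the temporal mean (degenerate for mean near 0).
    Zero-variance voxels are set to all-zero and logged, never NaN.
    """
    if mode not in ("zscore", "psc"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    dtype = series.data.dtype if series.data.dtype == np.float32 else np.float64
    y = series.masked().astype(np.float64)
    mean = y.mean(axis=0)
    out = np.zeros_like(series.data, dtype=dtype)
    if mode == "zscore":
        sd = y.std(axis=0, ddof=1)
        ok = sd > eps
        z = np.zeros_like(y)
        z[:, ok] = (y[:, ok] - mean[ok]) / sd[ok]
    else:
        ok = np.abs(mean) > eps
        z = np.zeros_like(y)
        z[:, ok] = 100.0 * (y[:, ok] - mean[ok]) / mean[ok]
    n_degenerate = int((~ok).sum())
    if n_degenerate:
        logger.warning("temporal_normalize: %d degenerate voxel(s) zeroed",
                       n_degenerate)
    out[series.mask] = z.T
    return series.with_data(out)


def smooth_spatial(series: BoldSeries, fwhm_mm: float,
                   mode: str = "constant") -> BoldSeries:
    """Frame-wise isotropic Gaussian smoothing.

    The FWHM (mm) is converted to per-axis sigmas in voxel units via the
    affine's voxel sizes, so anisotropic grids smooth isotropically in
    world space.  ``fwhm_mm = 0`` is the identity.  Boundary handling is
    plain zero-padded convolution by default (``mode="constant"``);
    ``"reflect"`` preserves the frame-wise sum.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return series
    sigmas = fwhm_mm * FWHM_TO_SIGMA / voxel_sizes(series.affine)
    out = ndimage.gaussian_filter(np.asarray(series.data, dtype=np.float32),
                                  sigma=tuple(sigmas) + (0.0,), mode=mode)
    return series.with_data(out)


def bandpass_matrix(y: np.ndarray, tr_s: float, low_hz: float,
                    high_hz: float) -> np.ndarray:
    """Hard Fourier band-pass of a (t, V) matrix along axis 0.

    Keeps rFFT bins with low_hz <= f <= high_hz; DC and all out-of-band
    bins (including Nyquist if out of band) are zeroed.
    """
    n = y.shape[0]
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0.0 <= low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz invalid: need "
            f"0 <= low < high < Nyquist {nyquist:g} Hz")
    freqs = np.fft.rfftfreq(n, tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz) & (freqs > 0)
    spectrum = sp_fft.rfft(y, axis=0)       # scipy.fft keeps float32 inputs
    spectrum[~keep] = 0.0
    return sp_fft.irfft(spectrum, n, axis=0)


def bandpass(series: BoldSeries, low_hz: float = 0.01,
             high_hz: float = 0.08) -> BoldSeries:
    """Per-voxel hard Fourier band-pass of the masked series."""
    filtered = bandpass_matrix(series.masked(), series.tr_s, low_hz, high_hz)
    out = np.zeros_like(series.data, dtype=filtered.dtype)
    out[series.mask] = filtered.T
    return series.with_data(out)


def preprocess_series(series: BoldSeries, design: NuisanceDesign,
                      fwhm_mm: float = 6.0,
                      band: tuple[float, float] = (0.01, 0.08),
                      normalize_mode: str = "zscore",
                      smooth_mode: str = "constant") -> BoldSeries:
    """Full conditioning chain: smooth -> normalize -> regress -> band-pass.

    Nuisance regression precedes the band-pass, which acts on the
    regression residuals.
    """
    out = smooth_spatial(series, fwhm_mm, mode=smooth_mode)
    out = temporal_normalize(out, mode=normalize_mode)
    out = regress_nuisance(out, design)
    return bandpass(out, *band)
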