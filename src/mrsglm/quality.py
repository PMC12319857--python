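"""Quality-control metrics and diagnostics for dynamic MRS.

Covers single-shot SNR (tNAA peak height over the noise-region standard
deviation), tNAA linewidth (FWHM) and its time-course, difference
spectrograms for visualising temporal variance, and exclusion rules for
scans with degraded lineshape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import detrend

from .core import (
    DynamicScan,
    MrsInputError,
    Spectrogram,
    Spectrum,
    ppm_slice,
)
from .preprocess import block_average

GAUSS_FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))


class SnrUndefinedError(MrsInputError):
    """Raised when the noise-region standard deviation is zero."""


@dataclass
class QcReport:
    """Per-scan quality metrics."""

    scan_id: str
    snr_per_transient: np.ndarray
    snr_median: float
    fwhm_ppm_timecourse: np.ndarray
    fwhm_smoothed_ppm: np.ndarray
    fwhm_pct_change: np.ndarray
    fwhm_mean_ppm: float
    excluded: bool = False
    reason: str = ""
    movement_advisory: bool = False


def snr_single_shot(
    spectrum: Spectrum,
    peak_ppm: float = 2.01,
    noise_ppm_range: Tuple[float, float] = (9.5, 11.5),
    peak_halfwidth: float = 0.05,
) -> float:
    """Peak-height SNR: real-part max near ``peak_ppm`` over the standard
    deviation of the linearly detrended real part in the noise region."""
    sl_peak = ppm_slice(spectrum.ppm, peak_ppm - peak_halfwidth,
                        peak_ppm + peak_halfwidth)
    sl_noise = ppm_slice(spectrum.ppm, *noise_ppm_range)
    peak = float(spectrum.real[sl_peak].max())
    noise = detrend(spectrum.real[sl_noise])
    sd = float(noise.std(ddof=1))
    if sd == 0:
        raise SnrUndefinedError("noise-region standard deviation is zero; "
                                "SNR undefined for a noiseless spectrum")
    return peak / sd


def fwhm_ppm(
    spectrum: Spectrum,
    peak_ppm: float = 2.01,
    search_halfwidth_ppm: float = 0.15,
) -> float:
    """Full width at half maximum of a peak, in ppm.

    A linear baseline spanning the search window's end points is removed
    before the half-height crossings are located by linear interpolation.
    """
    sl = ppm_slice(spectrum.ppm, peak_ppm - search_halfwidth_ppm,
                   peak_ppm + search_halfwidth_ppm)
    x = spectrum.ppm[sl]
    v = spectrum.real[sl].astype(float)
    if len(v) < 5:
        raise MrsInputError("search window too narrow for FWHM estimation")
    base = v[0] + (v[-1] - v[0]) * np.arange(len(v)) / (len(v) - 1)
    v = v - base
    i = int(np.argmax(v))
    if v[i] <= 0:
        raise MrsInputError("no positive peak in the search window")
    half = v[i] / 2.0

    def cross(idx_range) -> float:
        prev = i
        for j in idx_range:
            if v[j] <= half:
                x0, x1 = x[j], x[prev]
                y0, y1 = v[j], v[prev]
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0) if y1 != y0 else x0
            prev = j
        raise MrsInputError("no half-height crossing inside the search window")

    left = cross(range(i - 1, -1, -1))
    right = cross(range(i + 1, len(v)))
    return float(abs(left - right))


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with truncated edges."""
    if window <= 1:
        return x.astype(float).copy()
    half = window // 2
    out = np.empty(len(x), dtype=float)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def linewidth_timecourse(
    spectrogram: Spectrogram,
    peak_ppm: float = 2.01,
    smooth_window: int = 3,
    search_halfwidth_ppm: float = 0.15,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-dynamic tNAA FWHM, smoothed, and percent change from the first
    time point of the smoothed series."""
    if spectrogram.n_dynamics < 2:
        raise MrsInputError("need at least two dynamics")
    raw = np.array([
        fwhm_ppm(spectrogram.row(i), peak_ppm, search_halfwidth_ppm)
        for i in range(spectrogram.n_dynamics)
    ])
    smoothed = _moving_average(raw, smooth_window)
    pct = 100.0 * (smoothed - smoothed[0]) / smoothed[0]
    return raw, smoothed, pct


def difference_spectrogram(
    spectrogram: Spectrogram,
    lb_hz: float = 4.0,
    baseline: str = "linear",
) -> Spectrogram:
    """Dynamic-mean-subtracted spectrogram with Gaussian broadening and
    per-spectrum linear baseline removal, for visualising temporal
    variance."""
    if spectrogram.n_dynamics < 2:
        raise MrsInputError("need at least two dynamics")
    vals = spectrogram.values - spectrogram.values.mean(axis=0, keepdims=True)
    if lb_hz > 0:
        if spectrogram.transmitter_freq_mhz is None:
            raise MrsInputError("spectrogram lacks transmitter frequency; "
                                "cannot convert Hz broadening to bins")
        ppm_step = float(np.abs(np.median(np.diff(spectrogram.ppm))))
        hz_per_bin = ppm_step * spectrogram.transmitter_freq_mhz
        sigma_bins = (lb_hz / GAUSS_FWHM_TO_SD) / hz_per_bin
        vals = gaussian_filter1d(vals, sigma_bins, axis=1, mode="nearest")
    if baseline == "linear":
        n = vals.shape[1]
        x = np.arange(n) - (n - 1) / 2.0
        # least-squares line per row
        slope = (vals @ x) / (x @ x)
        intercept = vals.mean(axis=1)
        vals = vals - (intercept[:, None] + slope[:, None] * x[None, :])
    return Spectrogram(vals, spectrogram.ppm.copy(), spectrogram.times_s.copy(),
                       spectrogram.transmitter_freq_mhz)


def exclusion_check(
    report: QcReport,
    fwhm_limit_ppm: float = 0.07,
    fwhm_degradation_ppm: float = 0.02,
) -> Tuple[bool, str]:
    """Flag scans whose smoothed FWHM exceeds the absolute limit or whose
    degradation from the first time point exceeds the allowed amount.

    Both comparisons are strict: a value exactly at the limit is retained.
    """
    eps = 1e-12  # keep the boundary rule strict under float round-off
    sm = report.fwhm_smoothed_ppm
    if np.any(sm > fwhm_limit_ppm + eps):
        return True, f"fwhm_exceeds_limit:{float(sm.max()):.4f}>{fwhm_limit_ppm}"
    degradation = sm - sm[0]
    if np.any(degradation > fwhm_degradation_ppm + eps):
        return True, (f"fwhm_degradation:{float(degradation.max()):.4f}"
                      f">{fwhm_degradation_ppm}")
    return False, ""


def qc_scan(
    scan: DynamicScan,
    block_size: int = 50,
    peak_ppm: float = 2.01,
    noise_ppm_range: Tuple[float, float] = (9.5, 11.5),
    smooth_window: int = 3,
    alignment=None,
    fwhm_limit_ppm: float = 0.07,
    fwhm_degradation_ppm: float = 0.02,
) -> QcReport:
    """Compute the full QC report for one scan.

    Single-shot SNR is measured per transient and summarised by its
    median; linewidth is tracked on the block-averaged spectrogram.  If an
    :class:`~mrsglm.preprocess.AlignmentResult` is supplied, large
    transient-to-transient frequency jumps (> 5 Hz) raise an advisory
    movement flag.
    """
    spectra = scan.spectra()
    axis = scan.params.ppm_axis()
    sl_peak = ppm_slice(axis, peak_ppm - 0.05, peak_ppm + 0.05)
    sl_noise = ppm_slice(axis, *noise_ppm_range)
    peaks = np.real(spectra[:, sl_peak]).max(axis=1)
    noise = detrend(np.real(spectra[:, sl_noise]), axis=1)
    sds = noise.std(axis=1, ddof=1)
    if np.any(sds == 0):
        raise SnrUndefinedError("zero noise-region sd in at least one transient")
    snrs = peaks / sds

    spg = block_average(scan, block_size)
    raw, smoothed, pct = linewidth_timecourse(spg, peak_ppm, smooth_window)
    mean_fwhm = fwhm_ppm(scan.mean_spectrum(), peak_ppm)

    report = QcReport(
        scan_id=scan.scan_id,
        snr_per_transient=snrs,
        snr_median=float(np.median(snrs)),
        fwhm_ppm_timecourse=raw,
        fwhm_smoothed_ppm=smoothed,
        fwhm_pct_change=pct,
        fwhm_mean_ppm=mean_fwhm,
    )
    report.excluded, report.reason = exclusion_check(
        report, fwhm_limit_ppm, fwhm_degradation_ppm
    )
    if alignment is not None:
        jumps = np.abs(np.diff(alignment.freq_shift_hz))
        report.movement_advisory = bool(np.any(jumps > 5.0))
    return report


__all__ = [
    "QcReport",
    "SnrUndefinedError",
    "snr_single_shot",
    "fwhm_ppm",
    "linewidth_timecourse",
    "difference_spectrogram",
    "exclusion_check",
    "qc_scan",
]
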