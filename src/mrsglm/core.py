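"""Shared domain types and spectral-math primitives.

Conventions used throughout the package:

* FIDs are complex time-domain vectors sampled at the dwell time
  ``1 / spectral_width_hz``, starting at t = 0.
* Spectra are stored on a *descending* ppm axis (high -> low ppm), the
  standard in-vivo spectroscopy display convention.  All ppm range
  arguments are given as ``(low, high)`` and resolved internally.
* The chemical-shift axis is centred on ``ref_ppm`` (water, 4.65 ppm by
  default) and spans ``spectral_width_hz / transmitter_freq_mhz`` ppm.
  A resonance at frequency offset ``f`` Hz from the carrier appears at
  ``ref_ppm + f / transmitter_freq_mhz``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

LN2 = np.log(2.0)


class MrsInputError(ValueError):
    """Invalid argument or inconsistent input data."""


class MrsFormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class MrsRangeError(ValueError):
    """A requested ppm value or range falls outside the spectral axis."""


# ---------------------------------------------------------------------------
# acquisition parameters and task timing


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition parameters of a dynamic single-voxel MRS series.

    Parameters
    ----------
    n_points
        Number of complex samples per FID.
    spectral_width_hz
        Sampling bandwidth (1 / dwell time) in Hz.
    transmitter_freq_mhz
        Proton carrier frequency in MHz (~123.22 MHz on a 3 T system).
    te_ms, tr_ms
        Echo and repetition times in milliseconds.
    ref_ppm
        Chemical shift assigned to the centre of the spectral axis.
    """

    n_points: int = 2048
    spectral_width_hz: float = 2000.0
    transmitter_freq_mhz: float = 123.22
    te_ms: float = 28.0
    tr_ms: float = 2000.0
    ref_ppm: float = 4.65

    def __post_init__(self) -> None:
        if self.n_points <= 0:
            raise MrsInputError("n_points must be positive")
        if self.spectral_width_hz <= 0:
            raise MrsInputError("spectral_width_hz must be positive")
        if self.transmitter_freq_mhz <= 0:
            raise MrsInputError("transmitter_freq_mhz must be positive")

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.spectral_width_hz

    @property
    def tr_s(self) -> float:
        return self.tr_ms / 1000.0

    @property
    def ppm_span(self) -> float:
        return self.spectral_width_hz / self.transmitter_freq_mhz

    @property
    def hz_per_point(self) -> float:
        return self.spectral_width_hz / self.n_points

    @property
    def ppm_per_point(self) -> float:
        return self.hz_per_point / self.transmitter_freq_mhz

    def time_axis(self) -> np.ndarray:
        """Sample times of one FID in seconds, starting at 0."""
        return np.arange(self.n_points) * self.dwell_s

    def freq_axis_hz(self) -> np.ndarray:
        """Frequency offsets (Hz, ascending) matching ``np.fft.fftshift`` order."""
        return (np.arange(self.n_points) - self.n_points // 2) * self.hz_per_point

    def ppm_axis(self) -> np.ndarray:
        """Descending ppm axis centred on ``ref_ppm``."""
        asc = self.ref_ppm + self.freq_axis_hz() / self.transmitter_freq_mhz
        return asc[::-1].copy()

    def hz_to_ppm(self, f_hz: float) -> float:
        return self.ref_ppm + f_hz / self.transmitter_freq_mhz

    def ppm_to_hz(self, ppm: float) -> float:
        return (ppm - self.ref_ppm) * self.transmitter_freq_mhz


@dataclass(frozen=True)
class TaskDesign:
    """Rest / task / rest block timing of the functional paradigm.

    Defaults follow a 3 min rest, 8 min task, 14 min rest design
    (25 min total at TR 2 s -> 750 transients).
    """

    rest1_s: float = 180.0
    task_s: float = 480.0
    rest2_s: float = 840.0
    lag_s: float = 0.0

    def __post_init__(self) -> None:
        if min(self.rest1_s, self.task_s, self.rest2_s) < 0:
            raise MrsInputError("task phase durations must be >= 0")
        if self.lag_s < 0:
            raise MrsInputError("lag_s must be >= 0")

    @property
    def total_s(self) -> float:
        return self.rest1_s + self.task_s + self.rest2_s

    @property
    def task_onset_s(self) -> float:
        return self.rest1_s

    @property
    def task_offset_s(self) -> float:
        return self.rest1_s + self.task_s


# ---------------------------------------------------------------------------
# data containers


@dataclass
class Spectrum:
    """A frequency-domain signal on a (descending) ppm axis."""

    values: np.ndarray
    ppm: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.values.shape != self.ppm.shape:
            raise MrsInputError("values and ppm must have the same length")
        d = np.diff(self.ppm)
        if len(d) and not (np.all(d < 0) or np.all(d > 0)):
            raise MrsInputError("ppm axis must be strictly monotone")

    @property
    def real(self) -> np.ndarray:
        return np.real(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Spectrogram:
    """Real-valued dynamics x frequency matrix on a ppm axis.

    ``times_s`` holds the acquisition midpoint of each dynamic.
    ``transmitter_freq_mhz`` is carried along (when known) so that
    Hz-parameterised operations such as line broadening can convert to
    ppm-axis bins.
    """

    values: np.ndarray
    ppm: np.ndarray
    times_s: np.ndarray
    transmitter_freq_mhz: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.values.ndim != 2:
            raise MrsInputError("spectrogram values must be 2-D")
        if self.values.shape[1] != len(self.ppm):
            raise MrsInputError("column count must equal len(ppm)")
        if self.values.shape[0] != len(self.times_s):
            raise MrsInputError("row count must equal len(times_s)")
        if len(self.times_s) > 1 and not np.all(np.diff(self.times_s) > 0):
            raise MrsInputError("times_s must be strictly increasing")

    @property
    def n_dynamics(self) -> int:
        return self.values.shape[0]

    def row(self, i: int) -> Spectrum:
        return Spectrum(self.values[i].copy(), self.ppm.copy())

    def mean_spectrum(self) -> Spectrum:
        return Spectrum(self.values.mean(axis=0), self.ppm.copy())


@dataclass
class DynamicScan:
    """Complex time-domain transients with acquisition and task metadata."""

    fids: np.ndarray
    params: AcquisitionParams
    task: Optional[TaskDesign] = None
    scan_id: str = "scan"

    def __post_init__(self) -> None:
        self.fids = np.atleast_2d(np.asarray(self.fids, dtype=complex))
        if self.fids.shape[1] != self.params.n_points:
            raise MrsInputError(
                f"each FID must have {self.params.n_points} samples, "
                f"got {self.fids.shape[1]}"
            )
        if self.task is not None:
            dur = self.n_transients * self.params.tr_s
            if not np.isclose(dur, self.task.total_s, rtol=0, atol=self.params.tr_s / 2):
                raise MrsInputError(
                    f"n_transients * TR = {dur:.1f} s does not match the task "
                    f"duration {self.task.total_s:.1f} s"
                )

    @property
    def n_transients(self) -> int:
        return self.fids.shape[0]

    def times_s(self) -> np.ndarray:
        """Acquisition midpoint of each transient in seconds."""
        return (np.arange(self.n_transients) + 0.5) * self.params.tr_s

    def spectra(self) -> np.ndarray:
        """All transients transformed to the (descending-ppm) frequency domain."""
        return fids_to_display(self.fids)

    def mean_fid(self) -> np.ndarray:
        return self.fids.mean(axis=0)

    def mean_spectrum(self) -> Spectrum:
        return fid_to_spectrum(self.mean_fid(), self.params)

    def with_fids(self, fids: np.ndarray) -> "DynamicScan":
        return DynamicScan(fids, self.params, self.task, self.scan_id)

    def copy(self) -> "DynamicScan":
        return self.with_fids(self.fids.copy())


# ---------------------------------------------------------------------------
# Fourier transform plumbing


def fids_to_display(fids: np.ndarray) -> np.ndarray:
    """FFT of one or more FIDs, reordered to match the descending ppm axis."""
    spec = np.fft.fftshift(np.fft.fft(fids, axis=-1), axes=-1)
    return spec[..., ::-1].copy()


def display_to_fids(values: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fids_to_display`."""
    raw = np.fft.ifftshift(values[..., ::-1], axes=-1)
    return np.fft.ifft(raw, axis=-1)


def fid_to_spectrum(fid: np.ndarray, params: AcquisitionParams) -> Spectrum:
    """Discrete Fourier transform of a single FID onto the ppm axis."""
    fid = np.asarray(fid)
    if fid.ndim != 1 or len(fid) != params.n_points:
        raise MrsInputError(
            f"FID length {fid.shape} does not match n_points={params.n_points}"
        )
    return Spectrum(fids_to_display(fid.astype(complex)), params.ppm_axis())


def spectrum_to_fid(spectrum: Spectrum) -> np.ndarray:
    """Inverse transform of :func:`fid_to_spectrum` (full axis required)."""
    return display_to_fids(np.asarray(spectrum.values, dtype=complex))


def ppm_to_index(ppm_value: float, axis: np.ndarray) -> int:
    """Index of the axis point nearest ``ppm_value``; ties go to the lower index."""
    axis = np.asarray(axis, dtype=float)
    lo, hi = float(axis.min()), float(axis.max())
    half_bin = 0.5 * float(np.abs(np.median(np.diff(axis)))) if len(axis) > 1 else 0.0
    if ppm_value < lo - half_bin or ppm_value > hi + half_bin:
        raise MrsRangeError(
            f"{ppm_value} ppm outside axis range [{lo:.4f}, {hi:.4f}]"
        )
    return int(np.argmin(np.abs(axis - ppm_value)))


def ppm_slice(axis: np.ndarray, low: float, high: float) -> slice:
    """Slice of a descending ppm axis covering [low, high], nearest-bin inclusive.

    Bounds extending beyond the axis are clamped to the axis ends.
    """
    if low >= high:
        raise MrsInputError(f"need low < high, got ({low}, {high})")
    axis = np.asarray(axis, dtype=float)
    lo_ax, hi_ax = float(axis.min()), float(axis.max())
    if high < lo_ax or low > hi_ax:
        raise MrsRangeError(
            f"range ({low}, {high}) ppm does not overlap axis "
            f"[{lo_ax:.4f}, {hi_ax:.4f}]"
        )
    i_high = ppm_to_index(min(high, hi_ax), axis)
    i_low = ppm_to_index(max(low, lo_ax), axis)
    start, stop = min(i_high, i_low), max(i_high, i_low) + 1
    return slice(start, stop)


def gaussian_apodize(
    fid: np.ndarray, lb_hz: float, params: AcquisitionParams
) -> np.ndarray:
    """Multiply FID(s) by a Gaussian envelope adding ``lb_hz`` of spectral FWHM.

    The envelope is ``exp(-(pi * lb_hz * t)**2 / (4 ln 2))``: it equals 1 at
    t = 0 and its Fourier transform is a Gaussian whose full width at half
    maximum is exactly ``lb_hz``.  ``lb_hz = 0`` is the identity.
    """
    if lb_hz < 0:
        raise MrsInputError("lb_hz must be >= 0")
    fid = np.asarray(fid, dtype=complex)
    if lb_hz == 0:
        return fid.copy()
    t = params.time_axis()
    env = np.exp(-((np.pi * lb_hz * t) ** 2) / (4.0 * LN2))
    return fid * env


def apply_shift_phase(
    fids: np.ndarray,
    freq_shift_hz: np.ndarray | float,
    phase_deg: np.ndarray | float,
    params: AcquisitionParams,
) -> np.ndarray:
    """Apply frequency shift(s) and zero-order phase(s) to FID row(s).

    A positive ``freq_shift_hz`` moves spectral content towards higher
    frequency (higher ppm); ``phase_deg`` rotates the complex signal.
    """
    fids = np.atleast_2d(np.asarray(fids, dtype=complex))
    t = params.time_axis()
    df = np.atleast_1d(np.asarray(freq_shift_hz, dtype=float))[:, None]
    ph = np.deg2rad(np.atleast_1d(np.asarray(phase_deg, dtype=float)))[:, None]
    out = fids * np.exp(1j * (2.0 * np.pi * df * t[None, :] + ph))
    return out


__all__ = [
    "AcquisitionParams",
    "TaskDesign",
    "DynamicScan",
    "Spectrum",
    "Spectrogram",
    "MrsInputError",
    "MrsFormatError",
    "MrsRangeError",
    "fid_to_spectrum",
    "spectrum_to_fid",
    "fids_to_display",
    "display_to_fids",
    "ppm_to_index",
    "ppm_slice",
    "gaussian_apodize",
    "apply_shift_phase",
    "replace",
]
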