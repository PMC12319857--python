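"""Preprocessing chain for dynamic MRS series.

Stages, in the order they are applied:

1. per-transient frequency and zero-order phase alignment to a reference
   built from the scan's own mean spectrum (robust alignment to a target,
   least-absolute-deviation loss over a restricted ppm range);
2. a second alignment pass of the scan mean to a simple simulated
   three-singlet reference (2.01 / 3.03 / 3.22 ppm, 4 Hz Lorentzian), with
   the single correction applied back to every transient so all scans of a
   cohort share one frequency/phase frame;
3. amplitude normalisation to the tCr 3.03 ppm peak height of the dynamic
   mean spectrum;
4. either 50-transient block averaging (the conventional analysis path) or
   2 Hz Gaussian broadening, cropping to the 0-4.3 ppm analysis window and
   asymmetric least squares baseline correction (the spectral-GLM path).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import solveh_banded

from .core import (
    AcquisitionParams,
    DynamicScan,
    MrsInputError,
    Spectrogram,
    Spectrum,
    apply_shift_phase,
    fids_to_display,
    gaussian_apodize,
    ppm_slice,
)
from .synthdata import Resonance, _coefficient, _envelope


@dataclass
class AlignmentResult:
    """Per-transient corrections applied during alignment.

    ``freq_shift_hz`` and ``phase_deg`` are the corrections *applied* to
    each transient (multiplication by ``exp(i(2 pi df t + phi))``);
    applying the negated corrections to the corrected data restores the
    input.  ``converged`` is False where the search hit its bounds.
    """

    freq_shift_hz: np.ndarray
    phase_deg: np.ndarray
    converged: np.ndarray


@dataclass
class PreprocessConfig:
    align_ppm_range: Tuple[float, float] = (1.9, 4.0)
    align_max_shift_hz: float = 10.0
    align_max_phase_deg: float = 180.0
    second_pass: bool = True
    normalize: bool = True
    glm_lb_hz: float = 2.0
    glm_crop: Tuple[float, float] = (0.0, 4.3)
    asls_lam: float = 1e4
    asls_p: float = 1e-3
    asls_niter: int = 10
    block_size: int = 50


# ---------------------------------------------------------------------------
# reference construction


def make_reference_from_mean(
    scan: DynamicScan, ppm_range: Tuple[float, float] = (1.9, 4.0)
) -> Spectrum:
    """Mean uncorrected spectrum restricted to ``ppm_range``."""
    if scan.n_transients < 1:
        raise MrsInputError("scan has no transients")
    mean = scan.mean_spectrum()
    sl = ppm_slice(mean.ppm, *ppm_range)
    ref = Spectrum(mean.values[sl].copy(), mean.ppm[sl].copy())
    scale = np.abs(scan.spectra()[:, sl]).mean() if scan.n_transients else 0.0
    if scale > 0 and np.abs(ref.values).max() < 1e-9 * scale:
        warnings.warn("degenerate (near-zero) alignment reference", stacklevel=2)
    return ref


def synthetic_alignment_reference(params: AcquisitionParams) -> Spectrum:
    """Three equal-intensity singlets at 2.01/3.03/3.22 ppm with 4 Hz
    Lorentzian line broadening, on the acquisition ppm axis."""
    t = params.time_axis()
    fid = np.zeros(params.n_points, dtype=complex)
    for ppm in (2.01, 3.03, 3.22):
        r = Resonance(ppm, 1.0, lorentz_damping_hz=4.0, gauss_damping_hz=0.0)
        f = params.ppm_to_hz(ppm)
        fid += _coefficient(r, params) * np.exp(2j * np.pi * f * t) * _envelope(r, t)
    return Spectrum(fids_to_display(fid), params.ppm_axis())


def _reference_on_axis(reference: Spectrum, axis: np.ndarray, sl: slice) -> np.ndarray:
    """Reference values on ``axis[sl]`` (nearest-bin resampling if needed)."""
    target = axis[sl]
    if len(reference.ppm) == len(target) and np.allclose(reference.ppm, target):
        return np.asarray(reference.values, dtype=complex)
    if len(reference.ppm) == len(axis) and np.allclose(reference.ppm, axis):
        return np.asarray(reference.values[sl], dtype=complex)
    idx = np.abs(reference.ppm[None, :] - target[:, None]).argmin(axis=1)
    return np.asarray(reference.values, dtype=complex)[idx]


# ---------------------------------------------------------------------------
# alignment engine


def _l2_phase(spectra_range: np.ndarray, ref_range: np.ndarray) -> np.ndarray:
    """Phase (rad) minimising ||e^{-i phi} S - R||^2 per row."""
    inner = spectra_range @ np.conj(ref_range)
    return np.angle(inner)


def _lad_loss(spectra_range: np.ndarray, phi: np.ndarray, ref_range: np.ndarray
              ) -> np.ndarray:
    return np.abs(spectra_range * np.exp(-1j * phi)[:, None] - ref_range).sum(axis=1)


def _parabolic(x: np.ndarray, y0: np.ndarray, y1: np.ndarray, y2: np.ndarray,
               step: float) -> np.ndarray:
    """Vertex offset of a parabola through three equally spaced points."""
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 0.5 * (y0 - y2) / denom
    d = np.where(np.abs(denom) > 0, d, 0.0)
    return np.clip(d, -1.0, 1.0) * step


def align_transients(
    scan: DynamicScan,
    reference: Spectrum,
    ppm_range: Tuple[float, float] = (1.9, 4.0),
    max_shift_hz: float = 10.0,
    max_phase_deg: float = 180.0,
) -> Tuple[DynamicScan, AlignmentResult]:
    """Frequency/phase align every transient to the reference spectrum.

    Each transient's offset is initialised by a weighted linear fit to the
    unwrapped phase of ``s(t) * conj(ref(t))`` computed on band-limited
    FIDs, then refined on a least-absolute-deviation grid over the
    alignment ppm range with parabolic sub-grid interpolation.
    """
    params = scan.params
    t = params.time_axis()
    axis = params.ppm_axis()
    sl = ppm_slice(axis, *ppm_range)
    ref_range = _reference_on_axis(reference, axis, sl)

    # coarse shift from circular cross-correlation of magnitude spectra over
    # the alignment band (insensitive to phase and robust for multi-line
    # spectra), refined to sub-bin accuracy by parabolic interpolation
    disp = fids_to_display(scan.fids)
    S = np.abs(disp[:, sl])
    R = np.abs(ref_range)
    nb = S.shape[1]
    npad = 1 << int(np.ceil(np.log2(2 * nb)))
    corr = np.fft.ifft(
        np.fft.fft(S, npad, axis=1) * np.conj(np.fft.fft(R, npad))[None, :],
        axis=1,
    ).real
    lags = np.rint(np.fft.fftfreq(npad, 1.0 / npad)).astype(int)
    max_bins = max(1, int(np.ceil(max_shift_hz / params.hz_per_point)))
    allowed = np.flatnonzero(np.abs(lags) <= max_bins)
    j = allowed[corr[:, allowed].argmax(axis=1)]
    y0 = corr[np.arange(len(j)), (j - 1) % npad]
    y1 = corr[np.arange(len(j)), j]
    y2 = corr[np.arange(len(j)), (j + 1) % npad]
    sub = _parabolic(lags[j].astype(float), y0, y1, y2, 1.0)
    # a transient shifted by +df Hz sits at higher ppm, i.e. lower display
    # index, so the display-bin lag maps to frequency with a sign flip
    df0 = -(lags[j] + sub) * params.hz_per_point

    clipped = np.abs(df0) > max_shift_hz
    df0 = np.clip(df0, -max_shift_hz, max_shift_hz)

    # LAD grid polish around the init
    step = 0.1
    offsets = np.arange(-6, 7) * step
    base = scan.fids * np.exp(-2j * np.pi * df0[:, None] * t[None, :])
    losses = np.empty((scan.n_transients, len(offsets)))
    for j, e in enumerate(offsets):
        s = fids_to_display(base * np.exp(-2j * np.pi * e * t)[None, :])[:, sl]
        phi = _l2_phase(s, ref_range)
        losses[:, j] = _lad_loss(s, phi, ref_range)
    jmin = losses.argmin(axis=1)
    inner = np.clip(jmin, 1, len(offsets) - 2)
    delta = _parabolic(
        offsets[inner],
        losses[np.arange(len(jmin)), inner - 1],
        losses[np.arange(len(jmin)), inner],
        losses[np.arange(len(jmin)), inner + 1],
        step,
    )
    delta = np.where(jmin == inner, delta, 0.0)
    df = np.clip(df0 + offsets[jmin] + delta, -max_shift_hz, max_shift_hz)

    # final phase at the refined shift: L2 estimate + LAD polish
    shifted = scan.fids * np.exp(-2j * np.pi * df[:, None] * t[None, :])
    s_range = fids_to_display(shifted)[:, sl]
    phi = _l2_phase(s_range, ref_range)
    grid = np.deg2rad(np.arange(-12, 13) * 0.25)
    ploss = np.empty((scan.n_transients, len(grid)))
    for j, g in enumerate(grid):
        ploss[:, j] = _lad_loss(s_range, phi + g, ref_range)
    pj = ploss.argmin(axis=1)
    pin = np.clip(pj, 1, len(grid) - 2)
    pdelta = _parabolic(
        grid[pin],
        ploss[np.arange(len(pj)), pin - 1],
        ploss[np.arange(len(pj)), pin],
        ploss[np.arange(len(pj)), pin + 1],
        grid[1] - grid[0],
    )
    pdelta = np.where(pj == pin, pdelta, 0.0)
    phi = phi + grid[pj] + pdelta
    max_phase = np.deg2rad(max_phase_deg)
    phase_clipped = np.abs(phi) > max_phase
    phi = np.clip(phi, -max_phase, max_phase)

    corrected = shifted * np.exp(-1j * phi)[:, None]
    # applied corrections (what was multiplied in)
    result = AlignmentResult(
        freq_shift_hz=-df,
        phase_deg=-np.rad2deg(phi),
        converged=~(clipped | phase_clipped),
    )
    return scan.with_fids(corrected), result


def _grid_align_single(
    fid: np.ndarray,
    ref_range: np.ndarray,
    sl: slice,
    params: AcquisitionParams,
    max_shift_hz: float,
    coarse_step: float = 0.25,
) -> Tuple[float, float]:
    """Robust grid search of (shift, phase) for a single FID against a
    reference whose lineshape may differ (used by the second pass)."""
    t = params.time_axis()
    offsets = np.arange(-max_shift_hz, max_shift_hz + 1e-9, coarse_step)
    losses = np.empty(len(offsets))
    phis = np.empty(len(offsets))
    for j, e in enumerate(offsets):
        s = fids_to_display(fid * np.exp(-2j * np.pi * e * t))[sl]
        phi = float(np.angle(s @ np.conj(ref_range)))
        losses[j] = np.abs(s * np.exp(-1j * phi) - ref_range).sum()
        phis[j] = phi
    j = int(losses.argmin())
    jin = int(np.clip(j, 1, len(offsets) - 2))
    if j == jin:
        d = _parabolic(
            np.array([offsets[jin]]),
            np.array([losses[jin - 1]]),
            np.array([losses[jin]]),
            np.array([losses[jin + 1]]),
            coarse_step,
        )[0]
    else:
        d = 0.0
    df = float(np.clip(offsets[j] + d, -max_shift_hz, max_shift_hz))
    s = fids_to_display(fid * np.exp(-2j * np.pi * df * t))[sl]
    phi = float(np.angle(s @ np.conj(ref_range)))
    return df, phi


def second_pass_align(
    scan: DynamicScan,
    ppm_range: Tuple[float, float] = (1.9, 4.0),
    max_shift_hz: float = 10.0,
) -> Tuple[DynamicScan, Tuple[float, float]]:
    """Align the scan's dynamic mean to the simulated three-singlet
    reference and apply the single correction to every transient.

    Returns the corrected scan and the applied (freq_shift_hz, phase_deg).
    """
    params = scan.params
    axis = params.ppm_axis()
    sl = ppm_slice(axis, *ppm_range)
    ref = synthetic_alignment_reference(params)
    ref_range = np.asarray(ref.values[sl], dtype=complex)
    # match overall scale so the LAD loss is balanced
    mean_fid = scan.mean_fid()
    s = fids_to_display(mean_fid)[sl]
    scale = np.abs(s).sum() / max(np.abs(ref_range).sum(), 1e-30)
    df, phi = _grid_align_single(mean_fid, ref_range * scale, sl, params, max_shift_hz)
    corrected = apply_shift_phase(scan.fids, -df, -np.rad2deg(phi), params)
    return scan.with_fids(corrected), (-df, -float(np.rad2deg(phi)))


# ---------------------------------------------------------------------------
# normalisation / averaging / cropping


def tcr_peak_height(
    scan: DynamicScan, peak_ppm: float = 3.03, halfwidth: float = 0.05,
    mode: str = "real",
) -> float:
    """tCr peak height of the dynamic mean spectrum."""
    mean = scan.mean_spectrum()
    sl = ppm_slice(mean.ppm, peak_ppm - halfwidth, peak_ppm + halfwidth)
    vals = mean.real[sl] if mode == "real" else np.abs(mean.values[sl])
    return float(vals.max())


def normalize_tcr(
    scan: DynamicScan, peak_ppm: float = 3.03, halfwidth: float = 0.05,
    mode: str = "real",
) -> DynamicScan:
    """Divide all transients by the tCr peak height of the dynamic mean."""
    h = tcr_peak_height(scan, peak_ppm, halfwidth, mode)
    if h <= 0:
        raise MrsInputError(
            f"non-positive tCr peak height ({h:.3g}): alignment or phasing "
            "has likely failed"
        )
    return scan.with_fids(scan.fids / h)


def block_average(scan: DynamicScan, block_size: int) -> Spectrogram:
    """Average transients into temporal blocks; returns the real-part
    spectrogram of the block means, with block-midpoint times."""
    if block_size < 1:
        raise MrsInputError("block_size must be >= 1")
    n = scan.n_transients
    if n % block_size:
        raise MrsInputError(
            f"{n} transients not divisible by block_size {block_size} "
            f"(remainder {n % block_size})"
        )
    nb = n // block_size
    means = scan.fids.reshape(nb, block_size, -1).mean(axis=1)
    values = np.real(fids_to_display(means))
    times = (np.arange(nb) + 0.5) * block_size * scan.params.tr_s
    return Spectrogram(values, scan.params.ppm_axis(), times,
                       transmitter_freq_mhz=scan.params.transmitter_freq_mhz)


def crop_ppm(obj, low: float, high: float):
    """Crop a Spectrum or Spectrogram to [low, high] ppm (nearest-bin
    inclusive at both ends)."""
    if isinstance(obj, Spectrum):
        sl = ppm_slice(obj.ppm, low, high)
        return Spectrum(obj.values[sl].copy(), obj.ppm[sl].copy())
    if isinstance(obj, Spectrogram):
        sl = ppm_slice(obj.ppm, low, high)
        return Spectrogram(obj.values[:, sl].copy(), obj.ppm[sl].copy(),
                           obj.times_s.copy(), obj.transmitter_freq_mhz)
    raise TypeError(f"cannot crop {type(obj).__name__}")


# ---------------------------------------------------------------------------
# asymmetric least squares baseline


def _whittaker_banded(n: int, lam: float) -> np.ndarray:
    """Upper banded form of lam * D2' D2 for a length-n signal."""
    ab = np.zeros((3, n))
    # D2'D2 diagonals: main [1,5,6,...,6,5,1], off1 [-2,-4,...,-4,-2], off2 [1,...]
    main = np.full(n, 6.0)
    main[[0, -1]] = 1.0
    main[[1, -2]] = 5.0
    off1 = np.full(n - 1, -4.0)
    off1[[0, -1]] = -2.0
    off2 = np.full(n - 2, 1.0)
    ab[2, :] = lam * main
    ab[1, 1:] = lam * off1
    ab[0, 2:] = lam * off2
    return ab


def asls_baseline(
    y: np.ndarray,
    lam: float = 1e4,
    p_asym: float = 1e-3,
    n_iter: int = 10,
) -> Tuple[np.ndarray, np.ndarray]:
    """Asymmetric least squares (Whittaker) baseline of a real spectrum row.

    Minimises ``sum_i w_i (y_i - z_i)^2 + lam * sum (D2 z)^2`` with weights
    ``p_asym`` where y > z and ``1 - p_asym`` where y <= z, iterated until
    the weights stop changing or ``n_iter`` passes.  Returns
    ``(baseline, corrected)`` with ``corrected = y - baseline``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise MrsInputError("asls_baseline expects a 1-D row")
    if not np.all(np.isfinite(y)):
        raise MrsInputError("non-finite values in input")
    if lam <= 0:
        raise MrsInputError("lam must be > 0")
    if not 0 < p_asym < 1:
        raise MrsInputError("p_asym must be in (0, 1)")
    n = len(y)
    pen = _whittaker_banded(n, lam)
    w = np.ones(n)
    z = y.copy()
    for _ in range(max(n_iter, 1)):
        ab = pen.copy()
        ab[2, :] += w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p_asym, 1.0 - p_asym)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z, y - z


def asls_spectrogram(spg: Spectrogram, lam: float = 1e4, p_asym: float = 1e-3,
                     n_iter: int = 10) -> Spectrogram:
    """Row-wise ASLS correction of a spectrogram."""
    out = np.empty_like(spg.values)
    for i in range(spg.n_dynamics):
        _, out[i] = asls_baseline(spg.values[i], lam, p_asym, n_iter)
    return Spectrogram(out, spg.ppm.copy(), spg.times_s.copy(),
                       spg.transmitter_freq_mhz)


# ---------------------------------------------------------------------------
# full chain


@dataclass
class CohortPreprocessResult:
    mean: Spectrogram
    per_scan: List[Spectrogram]
    alignments: List[AlignmentResult]


def _align_chain(scan: DynamicScan, config: PreprocessConfig
                 ) -> Tuple[DynamicScan, AlignmentResult]:
    ref = make_reference_from_mean(scan, config.align_ppm_range)
    scan, result = align_transients(
        scan, ref, config.align_ppm_range,
        config.align_max_shift_hz, config.align_max_phase_deg,
    )
    if config.second_pass:
        scan, _ = second_pass_align(scan, config.align_ppm_range,
                                    config.align_max_shift_hz)
    if config.normalize:
        scan = normalize_tcr(scan)
    return scan, result


def _glm_spectrogram(scan: DynamicScan, config: PreprocessConfig,
                     apply_asls: bool = True) -> Spectrogram:
    params = scan.params
    fids = gaussian_apodize(scan.fids, config.glm_lb_hz, params)
    values = np.real(fids_to_display(fids))
    spg = Spectrogram(values, params.ppm_axis(), scan.times_s(),
                      transmitter_freq_mhz=params.transmitter_freq_mhz)
    spg = crop_ppm(spg, *config.glm_crop)
    if apply_asls:
        spg = asls_spectrogram(spg, config.asls_lam, config.asls_p,
                               config.asls_niter)
    return spg


def preprocess_scan(
    scan: DynamicScan,
    profile: str = "glm",
    config: Optional[PreprocessConfig] = None,
    apply_asls: bool = True,
) -> Tuple[Spectrogram, AlignmentResult]:
    """Run the full preprocessing chain on one scan.

    ``profile="block"`` yields the block-averaged spectrogram used by the
    conventional analysis; ``profile="glm"`` yields the transient-resolution
    broadened, cropped, baseline-corrected spectrogram consumed by the
    spectral GLM.
    """
    if profile not in ("glm", "block"):
        raise MrsInputError(f"unknown profile {profile!r}")
    config = config or PreprocessConfig()
    scan, result = _align_chain(scan, config)
    if profile == "block":
        return block_average(scan, config.block_size), result
    return _glm_spectrogram(scan, config, apply_asls), result


def preprocess_cohort(
    scans: Sequence[DynamicScan],
    profile: str = "glm",
    config: Optional[PreprocessConfig] = None,
    per_scan_asls: bool = True,
) -> CohortPreprocessResult:
    """Preprocess every scan, then average spectrograms transient-wise.

    For the GLM profile the baseline correction is applied to each
    per-scan spectrogram and, separately, to the cohort mean of the
    *uncorrected* spectrograms (mirroring an analysis run on
    participant-averaged data).  ``per_scan_asls=False`` skips the
    per-scan baseline correction (the returned per-scan spectrograms are
    then pre-baseline), which is cheaper when only the cohort mean is
    analysed.
    """
    config = config or PreprocessConfig()
    per_scan: List[Spectrogram] = []
    raw: List[np.ndarray] = []
    aligns: List[AlignmentResult] = []
    ppm_ref = None
    for scan in scans:
        scan2, res = _align_chain(scan, config)
        aligns.append(res)
        if profile == "block":
            spg = block_average(scan2, config.block_size)
            pre = spg
        else:
            pre = _glm_spectrogram(scan2, config, apply_asls=False)
            spg = asls_spectrogram(pre, config.asls_lam, config.asls_p,
                                   config.asls_niter) if per_scan_asls else pre
        if ppm_ref is None:
            ppm_ref = pre.ppm
            template = pre
        elif len(pre.ppm) != len(ppm_ref) or not np.allclose(pre.ppm, ppm_ref):
            warnings.warn("resampling scan onto the first scan's ppm axis")
            idx = np.abs(pre.ppm[None, :] - ppm_ref[:, None]).argmin(axis=1)
            pre = Spectrogram(pre.values[:, idx], ppm_ref.copy(),
                              pre.times_s.copy(), pre.transmitter_freq_mhz)
            spg = Spectrogram(spg.values[:, idx], ppm_ref.copy(),
                              spg.times_s.copy(), spg.transmitter_freq_mhz)
        per_scan.append(spg)
        raw.append(pre.values)
    mean_vals = np.mean(raw, axis=0)
    mean = Spectrogram(mean_vals, template.ppm.copy(), template.times_s.copy(),
                       template.transmitter_freq_mhz)
    if profile == "glm":
        mean = asls_spectrogram(mean, config.asls_lam, config.asls_p,
                                config.asls_niter)
    return CohortPreprocessResult(mean=mean, per_scan=per_scan, alignments=aligns)


__all__ = [
    "AlignmentResult",
    "PreprocessConfig",
    "CohortPreprocessResult",
    "make_reference_from_mean",
    "synthetic_alignment_reference",
    "align_transients",
    "second_pass_align",
    "tcr_peak_height",
    "normalize_tcr",
    "block_average",
    "crop_ppm",
    "asls_baseline",
    "asls_spectrogram",
    "preprocess_scan",
    "preprocess_cohort",
]
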