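"""Synthetic dynamic-MRS generation.

Produces :class:`~mrsglm.core.DynamicScan` objects with the statistical
structure of a prolonged-task fMRS experiment: task-locked metabolite
amplitude changes, a scalp-lipid artefact with a random per-scan phase and
slowly varying amplitude, a gradual linewidth drift, per-transient
frequency/phase jitter, and complex Gaussian noise calibrated to a target
single-shot SNR.

Each resonance contributes a Voigt line

    a(d) * exp(i 2 pi f t + i phi) * exp(-pi L t) * exp(-(pi G t)^2 / (4 ln2))

where ``L`` and ``G`` are the Lorentzian and Gaussian FWHM contributions in
Hz and ``a(d)`` is scaled by the resonance's dynamic response evaluated at
the transient's acquisition time.  Amplitudes are expressed as isolated
spectral peak heights relative to the tCr 3.03 ppm singlet.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Tuple, Union

import numpy as np

from .core import (
    LN2,
    AcquisitionParams,
    DynamicScan,
    MrsInputError,
    TaskDesign,
    fids_to_display,
    ppm_slice,
)

SeedLike = Union[int, np.random.SeedSequence, None]


# ---------------------------------------------------------------------------
# building blocks


@dataclass(frozen=True)
class Resonance:
    """A single spectral line of the simulation basis."""

    ppm: float
    amplitude: float
    lorentz_damping_hz: float = 4.0
    gauss_damping_hz: float = 3.2
    phase_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise MrsInputError("amplitude must be >= 0")
        if self.lorentz_damping_hz < 0 or self.gauss_damping_hz < 0:
            raise MrsInputError("damping values must be >= 0")


@dataclass(frozen=True)
class DynamicResponse:
    """Temporal modulation of a resonance amplitude across the experiment.

    shape
        ``constant`` (no task response), ``boxcar`` (0/1 during rest/task)
        or ``lagged_trapezoid`` (linear rise over ``lag_s`` after task
        onset, plateau, linear decay over ``decay_s`` after offset).
    effect_fraction
        Fractional amplitude change at full response, e.g. +0.20.
    """

    shape: str = "constant"
    effect_fraction: float = 0.0
    lag_s: float = 120.0
    decay_s: float = 120.0

    def __post_init__(self) -> None:
        if self.shape not in ("constant", "boxcar", "lagged_trapezoid"):
            raise MrsInputError(f"unknown response shape: {self.shape!r}")
        if self.lag_s < 0 or self.decay_s < 0:
            raise MrsInputError("lag_s and decay_s must be >= 0")

    def response(self, times_s: np.ndarray, task: TaskDesign) -> np.ndarray:
        """Unit response r(t) in [0, 1] at the given times."""
        t = np.asarray(times_s, dtype=float)
        if self.shape == "constant":
            return np.zeros_like(t)
        on, off = task.task_onset_s, task.task_offset_s
        if self.shape == "boxcar":
            return ((t >= on) & (t < off)).astype(float)
        if self.lag_s > 0:
            rise = np.clip((t - on) / self.lag_s, 0.0, 1.0)
        else:
            rise = (t >= on).astype(float)
        level_at_off = min((off - on) / self.lag_s, 1.0) if self.lag_s > 0 else 1.0
        if self.decay_s > 0:
            fall = level_at_off * np.clip(1.0 - (t - off) / self.decay_s, 0.0, 1.0)
        else:
            fall = np.zeros_like(t)
        r = np.where(t < on, 0.0, np.where(t < off, rise, fall))
        return r

    def amplitude_factor(self, times_s: np.ndarray, task: TaskDesign) -> np.ndarray:
        return 1.0 + self.effect_fraction * self.response(times_s, task)


@dataclass
class TableEntry:
    name: str
    resonances: List[Resonance]
    response: DynamicResponse = field(default_factory=DynamicResponse)


@dataclass
class ResonanceTable:
    """Named groups of resonances with their dynamic responses."""

    entries: List[TableEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise MrsInputError("entry names must be unique")

    def __getitem__(self, name: str) -> TableEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)

    def names(self) -> List[str]:
        return [e.name for e in self.entries]


@dataclass
class ConfoundSpec:
    """Confound structure of a simulated scan.

    All amplitude fractions are relative to the tCr 3.03 ppm peak height.
    ``lipid_phase_deg = None`` draws one uniform phase per scan;
    ``lipid_mod_timescale_s`` sets the smoothness of the slow random
    modulation of the lipid amplitude within a scan (the modulation is
    normalised so its maximum excursion from the scan mean equals
    ``lipid_amplitude_frac`` of tCr).  ``drift_fwhm_frac`` is the
    fractional linewidth increase reached at the final transient (linear
    ramp applied to both damping constants).
    """

    lipid_amplitude_frac: float = 0.15
    lipid_ppm_range: Tuple[float, float] = (1.0, 1.5)
    lipid_phase_deg: Optional[float] = None
    lipid_mod_timescale_s: float = 120.0
    drift_fwhm_frac: float = 0.2
    freq_jitter_sd_hz: float = 1.0
    phase_jitter_sd_deg: float = 5.0
    noise_sd: float = 0.0
    seed: SeedLike = None

    def __post_init__(self) -> None:
        for name in ("lipid_amplitude_frac", "drift_fwhm_frac",
                     "freq_jitter_sd_hz", "phase_jitter_sd_deg", "noise_sd"):
            if getattr(self, name) < 0:
                raise MrsInputError(f"{name} must be >= 0")


def no_confounds(noise_sd: float = 0.0, seed: SeedLike = None) -> ConfoundSpec:
    """A ConfoundSpec with every confound switched off (optionally noise on)."""
    return ConfoundSpec(
        lipid_amplitude_frac=0.0,
        drift_fwhm_frac=0.0,
        freq_jitter_sd_hz=0.0,
        phase_jitter_sd_deg=0.0,
        noise_sd=noise_sd,
        seed=seed,
    )


# lipid artefact: three broad Gaussian-damped lines spanning 1-1.5 ppm that
# share a single per-scan phase
LIPID_RESONANCES = [
    Resonance(1.10, 0.6, lorentz_damping_hz=0.0, gauss_damping_hz=25.0),
    Resonance(1.30, 1.0, lorentz_damping_hz=0.0, gauss_damping_hz=25.0),
    Resonance(1.45, 0.7, lorentz_damping_hz=0.0, gauss_damping_hz=25.0),
]


def default_table(
    lactate_effect: float = 0.20,
    glutamate_effect: float = 0.02,
    aspartate_effect: float = -0.04,
) -> ResonanceTable:
    """Default resonance table emulating a short-TE motor-cortex spectrum.

    Amplitudes are spectral peak heights relative to tCr = 1.  The default
    dynamic responses encode a lagged +20% lactate rise, a +2% glutamate
    boxcar and a lagged -4% aspartate decrease; pass 0 to disable.
    """

    def res(ppm: float, amp: float) -> Resonance:
        return Resonance(ppm, amp)

    lagged = lambda f: DynamicResponse("lagged_trapezoid", f) if f else DynamicResponse()
    boxcar = lambda f: DynamicResponse("boxcar", f) if f else DynamicResponse()
    return ResonanceTable(
        [
            TableEntry("tNAA", [res(2.01, 1.3)]),
            TableEntry("tCr", [res(3.03, 1.0), res(3.92, 0.65)]),
            TableEntry("tCho", [res(3.22, 0.9)]),
            TableEntry(
                "lactate", [res(1.28, 0.05), res(1.35, 0.05)], lagged(lactate_effect)
            ),
            TableEntry(
                "glutamate",
                [res(2.35, 0.45), res(2.08, 0.25), res(2.12, 0.25)],
                boxcar(glutamate_effect),
            ),
            TableEntry(
                "aspartate",
                [res(2.74, 0.12), res(2.78, 0.12)],
                lagged(aspartate_effect),
            ),
            TableEntry("myo-inositol", [res(3.55, 0.5), res(3.59, 0.45)]),
        ]
    )


# ---------------------------------------------------------------------------
# low-level synthesis


def _envelope(res: Resonance, t: np.ndarray, scale: np.ndarray | float = 1.0):
    """Voigt decay envelope, with the damping constants scaled by ``scale``."""
    scale = np.asarray(scale, dtype=float)
    lt = np.multiply.outer(scale, t) if scale.ndim else scale * t
    return np.exp(
        -np.pi * res.lorentz_damping_hz * lt
        - (np.pi * res.gauss_damping_hz * lt) ** 2 / (4.0 * LN2)
    )


def peak_height(res: Resonance, params: AcquisitionParams) -> float:
    """Spectral peak height of a unit-coefficient line (DFT value on resonance)."""
    return float(_envelope(res, params.time_axis()).sum())


def _coefficient(res: Resonance, params: AcquisitionParams) -> complex:
    """Time-domain coefficient making the isolated peak height equal amplitude."""
    h = peak_height(res, params)
    return res.amplitude / h * np.exp(1j * np.deg2rad(res.phase_deg))


def table_peak_height(table: ResonanceTable, name: str, ppm_window: float,
                      params: AcquisitionParams) -> float:
    """Noiseless rest-state peak height of a named entry near its first line."""
    entry = table[name]
    fid = np.zeros(params.n_points, dtype=complex)
    t = params.time_axis()
    for r in entry.resonances:
        f = params.ppm_to_hz(r.ppm)
        fid += _coefficient(r, params) * np.exp(2j * np.pi * f * t) * _envelope(r, t)
    spec = fids_to_display(fid)
    axis = params.ppm_axis()
    sl = ppm_slice(axis, entry.resonances[0].ppm - ppm_window,
                   entry.resonances[0].ppm + ppm_window)
    return float(np.real(spec[sl]).max())


def _lipid_scale(confounds: ConfoundSpec, tcr_height: float,
                 params: AcquisitionParams, phase_deg: float) -> float:
    """Scale factor making the *observed* lipid excursion match the spec.

    The artefact amplitude is stated as a fraction of the tCr peak height
    as seen in the real-part spectrum, so the calibration accounts for the
    scan's zero-order lipid phase: the scale is chosen such that the
    maximum absolute real part of the phased lipid hump equals
    ``lipid_amplitude_frac`` x tCr peak height."""
    t = params.time_axis()
    fid = np.zeros(params.n_points, dtype=complex)
    for r in LIPID_RESONANCES:
        f = params.ppm_to_hz(r.ppm)
        fid += _coefficient(r, params) * np.exp(2j * np.pi * f * t) * _envelope(r, t)
    spec = fids_to_display(fid) * np.exp(1j * np.deg2rad(phase_deg))
    sl = ppm_slice(params.ppm_axis(), *confounds.lipid_ppm_range)
    h = float(np.abs(np.real(spec[sl])).max())
    if h <= 0:
        raise MrsInputError("degenerate lipid lineshape")
    return confounds.lipid_amplitude_frac * tcr_height / h


def _smooth_random_mod(n: int, timescale_pts: float, rng: np.random.Generator
                       ) -> np.ndarray:
    """Zero-mean smooth random waveform normalised to max |w| = 1."""
    g = rng.standard_normal(n)
    if timescale_pts > 0:
        k = np.arange(-int(3 * timescale_pts), int(3 * timescale_pts) + 1)
        kern = np.exp(-0.5 * (k / timescale_pts) ** 2)
        kern /= kern.sum()
        g = np.convolve(np.pad(g, len(k) // 2, mode="wrap"), kern, mode="valid")[:n]
    g = g - g.mean()
    m = np.abs(g).max()
    return g / m if m > 0 else g


def simulate_scan(
    table: ResonanceTable,
    confounds: ConfoundSpec,
    params: AcquisitionParams = AcquisitionParams(),
    task: TaskDesign = TaskDesign(),
    n_transients: int = 750,
    seed: SeedLike = None,
    scan_id: str = "sim",
) -> DynamicScan:
    """Simulate a dynamic scan; fully reproducible from the seed.

    The seed argument takes precedence over ``confounds.seed``.
    """
    dur = n_transients * params.tr_s
    if not np.isclose(dur, task.total_s, atol=params.tr_s / 2):
        raise MrsInputError(
            f"n_transients * TR = {dur:.1f} s inconsistent with task "
            f"duration {task.total_s:.1f} s"
        )
    if seed is None:
        seed = confounds.seed
    rng = np.random.default_rng(seed)

    t = params.time_axis()
    times = (np.arange(n_transients) + 0.5) * params.tr_s
    drift = 1.0 + confounds.drift_fwhm_frac * np.arange(n_transients) / max(
        n_transients - 1, 1
    )

    fids = np.zeros((n_transients, params.n_points), dtype=complex)

    # metabolites, grouped by damping pair so the drift-scaled envelope is
    # computed once per group
    groups: dict = {}
    for entry in table.entries:
        fac = entry.response.amplitude_factor(times, task)
        for r in entry.resonances:
            key = (r.lorentz_damping_hz, r.gauss_damping_hz)
            groups.setdefault(key, []).append((r, fac))
    for (L, G), members in groups.items():
        proto = Resonance(0.0, 0.0, L, G)
        env = _envelope(proto, t, drift)  # (n_transients, n_points)
        P = np.zeros((len(members), params.n_points), dtype=complex)
        A = np.zeros((n_transients, len(members)))
        for k, (r, fac) in enumerate(members):
            f = params.ppm_to_hz(r.ppm)
            P[k] = _coefficient(r, params) * np.exp(2j * np.pi * f * t)
            A[:, k] = fac
        fids += (A @ P) * env

    # lipid artefact: shared per-scan phase, slowly varying amplitude
    if confounds.lipid_amplitude_frac > 0:
        if "tCr" not in table:
            raise MrsInputError("lipid amplitude is relative to tCr: table "
                                "needs a tCr entry")
        tcr_h = table_peak_height(table, "tCr", 0.05, params)
        if confounds.lipid_phase_deg is None:
            phase = rng.uniform(0.0, 360.0)
        else:
            phase = confounds.lipid_phase_deg
        scale = _lipid_scale(confounds, tcr_h, params, phase)
        mod_pts = confounds.lipid_mod_timescale_s / params.tr_s
        w = _smooth_random_mod(n_transients, mod_pts, rng)
        amp = scale * (1.0 + w)
        proto = LIPID_RESONANCES[0]
        env = _envelope(proto, t, drift)
        P = np.zeros((len(LIPID_RESONANCES), params.n_points), dtype=complex)
        for k, r in enumerate(LIPID_RESONANCES):
            f = params.ppm_to_hz(r.ppm)
            P[k] = _coefficient(r, params) * np.exp(2j * np.pi * f * t)
        shape = P.sum(axis=0) * np.exp(1j * np.deg2rad(phase))
        fids += np.outer(amp, shape) * env

    # per-transient frequency / phase jitter
    if confounds.freq_jitter_sd_hz > 0 or confounds.phase_jitter_sd_deg > 0:
        df = rng.normal(0.0, confounds.freq_jitter_sd_hz, n_transients)
        dp = np.deg2rad(rng.normal(0.0, confounds.phase_jitter_sd_deg, n_transients))
        fids *= np.exp(1j * (2 * np.pi * df[:, None] * t[None, :] + dp[:, None]))

    # complex Gaussian noise
    if confounds.noise_sd > 0:
        fids += confounds.noise_sd * (
            rng.standard_normal(fids.shape) + 1j * rng.standard_normal(fids.shape)
        )

    return DynamicScan(fids, params, task, scan_id)


def simulate_cohort(
    n_scans: int,
    table: ResonanceTable,
    confounds: ConfoundSpec,
    params: AcquisitionParams = AcquisitionParams(),
    task: TaskDesign = TaskDesign(),
    n_transients: int = 750,
    seed: SeedLike = 0,
) -> List[DynamicScan]:
    """Simulate ``n_scans`` scans differing only in their RNG streams."""
    if n_scans < 1:
        raise MrsInputError("n_scans must be >= 1")
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    children = seed.spawn(n_scans)
    return [
        simulate_scan(
            table, confounds, params, task, n_transients,
            seed=children[i], scan_id=f"sub-{i + 1:02d}",
        )
        for i in range(n_scans)
    ]


def calibrate_noise(
    table: ResonanceTable,
    params: AcquisitionParams = AcquisitionParams(),
    target_snr: float = 31.0,
) -> float:
    """Time-domain noise sd giving the requested single-shot spectral SNR.

    SNR is defined as the noiseless tNAA spectral peak height divided by the
    frequency-domain noise standard deviation (real part).  Complex white
    noise of per-point sd ``sigma`` has a real-part spectral sd of
    ``sigma * sqrt(n_points)`` under an unnormalised FFT.
    """
    if target_snr <= 0:
        raise MrsInputError("target_snr must be > 0")
    if "tNAA" not in table:
        raise MrsInputError("table has no tNAA entry")
    h = table_peak_height(table, "tNAA", 0.05, params)
    return float(h / (target_snr * np.sqrt(params.n_points)))


def study_confounds(target_snr: float = 31.0,
                    table: Optional[ResonanceTable] = None,
                    params: AcquisitionParams = AcquisitionParams(),
                    **overrides) -> ConfoundSpec:
    """Default confound set: lipid 15% of tCr, 20% linewidth drift,
    1 Hz / 5 deg jitter, noise calibrated to single-shot SNR 31."""
    if table is None:
        table = default_table()
    spec = ConfoundSpec(noise_sd=calibrate_noise(table, params, target_snr))
    for k, v in overrides.items():
        setattr(spec, k, v)
    return spec


# ---------------------------------------------------------------------------
# scenario (de)serialisation


def _plain(obj):
    """Recursively convert numpy scalars so the dict is YAML/JSON-safe."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.random.SeedSequence):
        return obj.entropy
    return obj


def scenario_to_dict(table: ResonanceTable, confounds: ConfoundSpec,
                     params: AcquisitionParams, task: TaskDesign,
                     n_transients: int, n_scans: int = 1) -> dict:
    return _plain({
        "params": asdict(params),
        "task": asdict(task),
        "n_transients": n_transients,
        "n_scans": n_scans,
        "confounds": asdict(confounds),
        "table": [
            {
                "name": e.name,
                "resonances": [asdict(r) for r in e.resonances],
                "response": asdict(e.response),
            }
            for e in table.entries
        ],
    })


def scenario_from_dict(d: dict):
    params = AcquisitionParams(**d["params"])
    task = TaskDesign(**d["task"])
    confounds = ConfoundSpec(**d["confounds"])
    table = ResonanceTable(
        [
            TableEntry(
                e["name"],
                [Resonance(**r) for r in e["resonances"]],
                DynamicResponse(**e["response"]),
            )
            for e in d["table"]
        ]
    )
    return table, confounds, params, task, int(d["n_transients"]), int(d.get("n_scans", 1))


__all__ = [
    "Resonance",
    "DynamicResponse",
    "TableEntry",
    "ResonanceTable",
    "ConfoundSpec",
    "no_confounds",
    "default_table",
    "simulate_scan",
    "simulate_cohort",
    "calibrate_noise",
    "study_confounds",
    "table_peak_height",
    "peak_height",
    "scenario_to_dict",
    "scenario_from_dict",
    "LIPID_RESONANCES",
]
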