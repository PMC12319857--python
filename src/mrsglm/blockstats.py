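"""Conventional block-averaged task-vs-rest statistics.

Metabolite levels are approximated by integrals of the baseline-corrected
real spectrum over fixed ppm windows — an intentionally simple *proxy* for
full basis-set fitting, adequate for simulated data where the underlying
resonances are known.  Proxy time-courses over the block-averaged dynamics
are compared between task and rest blocks with a pooled-variance two-sample
Student t-test, under two averaging schemes: levels measured on the
cohort-mean spectrogram (scheme A) or measured per scan and then averaged
(scheme B).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import MrsInputError, Spectrogram, Spectrum, TaskDesign, ppm_slice
from .preprocess import asls_baseline
from .spectral_glm import t_to_p

#: Default integration windows (low, high) in ppm for the proxy levels.
DEFAULT_RANGES: Dict[str, Tuple[float, float]] = {
    "lactate": (1.24, 1.40),
    "aspartate": (2.70, 2.82),
    "glutamate": (2.30, 2.40),
    "tNAA": (1.95, 2.07),
}


@dataclass
class MetaboliteTimecourse:
    """Proxy metabolite level per dynamic, with the task-block mask."""

    name: str
    values: np.ndarray
    times_s: np.ndarray
    task_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.task_mask = np.asarray(self.task_mask, dtype=bool)
        if not (len(self.values) == len(self.times_s) == len(self.task_mask)):
            raise MrsInputError("timecourse arrays must share a length")


@dataclass
class TaskRestTest:
    """Pooled-variance two-sample Student t-test between task and rest."""

    t: float
    df: int
    p: float
    mean_task: float
    mean_rest: float
    pct_change: float
    degenerate: bool = False


def proxy_level(
    spectrum: Spectrum,
    ppm_range: Tuple[float, float],
    baseline_correct: bool = True,
    asls_lam: float = 1e4,
    asls_p: float = 1e-3,
) -> float:
    """Integral of the (baseline-corrected) real part over ``ppm_range``.

    The integral uses the ppm bin width, so the level is in
    amplitude x ppm units; with tCr-normalised input it is tCr-relative.
    """
    vals = spectrum.real.astype(float)
    if baseline_correct:
        _, vals = asls_baseline(vals, asls_lam, asls_p)
    sl = ppm_slice(spectrum.ppm, *ppm_range)
    step = float(np.abs(np.median(np.diff(spectrum.ppm))))
    return float(vals[sl].sum() * step)


def assign_task_blocks(
    task: TaskDesign,
    times_s: np.ndarray,
    shift_blocks: int = 0,
) -> np.ndarray:
    """Task mask over dynamics: a dynamic is "task" iff its midpoint lies in
    [rest1, rest1 + task), shifted by ``shift_blocks`` whole dynamics.

    For 15 dynamics of 100 s with a 180-660 s task this yields 5 task and
    10 rest dynamics (the df = 13 geometry of the printed tests).
    """
    t = np.asarray(times_s, dtype=float)
    mask = (t >= task.task_onset_s) & (t < task.task_offset_s)
    if shift_blocks:
        shifted = np.zeros_like(mask)
        if shift_blocks > 0:
            shifted[shift_blocks:] = mask[:-shift_blocks]
        else:
            shifted[:shift_blocks] = mask[-shift_blocks:]
        mask = shifted
    if mask.all() or not mask.any():
        raise MrsInputError("task mask must leave both task and rest groups "
                            "non-empty")
    return mask


def metabolite_timecourses(
    spectrogram: Spectrogram,
    task: TaskDesign,
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    shift_blocks: int = 0,
    baseline_correct: bool = True,
) -> Dict[str, MetaboliteTimecourse]:
    """Proxy time-courses for each metabolite window over the dynamics."""
    ranges = ranges or DEFAULT_RANGES
    mask = assign_task_blocks(task, spectrogram.times_s, shift_blocks)
    step = float(np.abs(np.median(np.diff(spectrogram.ppm))))
    rows = spectrogram.values
    if baseline_correct:  # correct each row once, shared by all windows
        rows = np.vstack([asls_baseline(r)[1] for r in rows])
    out = {}
    for name, rng in ranges.items():
        sl = ppm_slice(spectrogram.ppm, *rng)
        levels = rows[:, sl].sum(axis=1) * step
        out[name] = MetaboliteTimecourse(name, levels, spectrogram.times_s.copy(),
                                         mask.copy())
    return out


def task_rest_ttest(tc: MetaboliteTimecourse) -> TaskRestTest:
    """Pooled-variance Student t between task and rest levels."""
    a = tc.values[tc.task_mask]
    b = tc.values[~tc.task_mask]
    if len(a) < 1 or len(b) < 1:
        raise MrsInputError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    if df < 1:
        raise MrsInputError("not enough data points for a t-test")
    var_a = a.var(ddof=1) if n1 > 1 else 0.0
    var_b = b.var(ddof=1) if n2 > 1 else 0.0
    sp2 = ((n1 - 1) * var_a + (n2 - 1) * var_b) / df
    mean_task, mean_rest = float(a.mean()), float(b.mean())
    diff = mean_task - mean_rest
    pct = 100.0 * diff / mean_rest if mean_rest != 0 else np.nan
    if sp2 <= 0:
        return TaskRestTest(np.nan, df, np.nan, mean_task, mean_rest, pct,
                            degenerate=True)
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return TaskRestTest(float(t), df, float(t_to_p(t, df)), mean_task,
                        mean_rest, pct)


@dataclass
class SchemeComparison:
    """Scheme A (cohort-mean spectrum) vs scheme B (per-scan, then averaged)."""

    scheme_a: Dict[str, MetaboliteTimecourse]
    scheme_b_mean: Dict[str, MetaboliteTimecourse]
    scheme_b_se: Dict[str, np.ndarray]
    per_scan: Dict[str, np.ndarray]  # name -> (n_scans, n_dynamics)


def averaging_schemes(
    per_scan_spectrograms: Sequence[Spectrogram],
    task: TaskDesign,
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    shift_blocks: int = 0,
) -> SchemeComparison:
    """Compute both cohort averaging schemes from per-scan spectrograms."""
    if len(per_scan_spectrograms) < 1:
        raise MrsInputError("need at least one scan")
    ranges = ranges or DEFAULT_RANGES
    template = per_scan_spectrograms[0]
    mean_vals = np.mean([s.values for s in per_scan_spectrograms], axis=0)
    mean_spg = Spectrogram(mean_vals, template.ppm.copy(),
                           template.times_s.copy(),
                           template.transmitter_freq_mhz)
    scheme_a = metabolite_timecourses(mean_spg, task, ranges, shift_blocks)

    per_scan_levels: Dict[str, List[np.ndarray]] = {n: [] for n in ranges}
    for spg in per_scan_spectrograms:
        tcs = metabolite_timecourses(spg, task, ranges, shift_blocks)
        for n in ranges:
            per_scan_levels[n].append(tcs[n].values)
    scheme_b_mean, scheme_b_se, stacked = {}, {}, {}
    mask = assign_task_blocks(task, template.times_s, shift_blocks)
    n_scans = len(per_scan_spectrograms)
    for n in ranges:
        arr = np.vstack(per_scan_levels[n])
        stacked[n] = arr
        scheme_b_mean[n] = MetaboliteTimecourse(
            n, arr.mean(axis=0), template.times_s.copy(), mask.copy()
        )
        scheme_b_se[n] = arr.std(axis=0, ddof=1) / np.sqrt(n_scans) \
            if n_scans > 1 else np.zeros(arr.shape[1])
    return SchemeComparison(scheme_a, scheme_b_mean, scheme_b_se, stacked)


__all__ = [
    "DEFAULT_RANGES",
    "MetaboliteTimecourse",
    "TaskRestTest",
    "SchemeComparison",
    "proxy_level",
    "assign_task_blocks",
    "metabolite_timecourses",
    "task_rest_ttest",
    "averaging_schemes",
]
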