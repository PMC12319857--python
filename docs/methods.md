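# Methods

`mrsglm` analyses dynamic (functional) single-voxel ¹H-MRS series: a time
series of complex FIDs acquired every TR while a participant rests, performs
a task, and rests again.  The package implements two complementary analyses
on top of a shared preprocessing chain, together with a quality-control
layer and a synthetic-data generator used throughout the test suite.

## Data model

A `DynamicScan` holds an `n_transients × n_points` complex FID matrix plus
acquisition parameters (defaults: 2048 complex points, 2000 Hz spectral
width, 123.22 MHz proton carrier — a 3 T system — TE 28 ms, TR 2 s) and the
task timing (defaults: 3 min rest, 8 min task, 14 min rest; 750 transients,
25 min).  Spectra live on a descending ppm axis referenced to water at
4.65 ppm; the axis spans `spectral_width / transmitter_freq` = 16.23 ppm.
A `Spectrogram` is the real-valued dynamics × frequency matrix the
statistics consume.

## Preprocessing

1. **Per-transient frequency/phase alignment.**  Each transient is aligned
   to a reference built from the scan's own mean spectrum restricted to
   1.9–4.0 ppm (the strongest metabolite signals).  The estimator
   initialises the frequency offset by FFT cross-correlation of band
   magnitude spectra (insensitive to phase and robust for multi-line
   spectra) with parabolic sub-bin interpolation, then refines (Δf, Δφ) on
   a least-absolute-deviation grid in the frequency domain (0.1 Hz / 0.25°
   steps, parabolic refinement), with the zero-order phase initialised at
   its least-squares optimum.  Corrections are applied in the time domain.
   Two simpler estimators were tried and rejected during development:
   unwrapped-phase regression of `s(t)·conj(ref(t))` suffers 2π unwrap
   slips at the beat nulls of multi-line FIDs, and the lag-one (pulse-pair)
   phase-increment estimator is biased by cross-terms between resonances.
   Measured accuracy of the final estimator on simulated scans: ≤0.01 Hz /
   ≤0.1° noise-free; at single-shot SNR 31, >95% of transients recover an
   injected offset within 0.3 Hz / 3°.  Defaults: search bounded at
   ±10 Hz / ±180°; transients that hit the bounds are flagged
   `converged=False`.
2. **Second-pass alignment.**  The scan's dynamic mean is aligned (bounded
   grid search, LAD loss) to a simulated reference of three equal-intensity
   singlets at 2.01, 3.03 and 3.22 ppm with 4 Hz Lorentzian broadening, and
   the single correction is applied back to every transient.  This puts all
   scans of a cohort in one frequency/phase frame.
3. **tCr normalisation.**  All transients are divided by the real-part peak
   height within 3.03 ± 0.05 ppm of the dynamic mean spectrum.  The window
   half-width (0.05 ppm) is our choice; the real part (rather than
   magnitude) matches the phased-spectrum convention used everywhere else.
4. **Analysis profiles.**  The *block* profile averages 50 consecutive
   transients (750 → 15 dynamics) to raise spectral SNR for the
   conventional analysis.  The *glm* profile applies 2 Hz Gaussian line
   broadening (envelope `exp(−(π·lb·t)²/(4 ln 2))`, so the added spectral
   FWHM equals `lb` exactly), crops to the 0–4.3 ppm analysis window
   (nearest-bin inclusive at both ends, 544 points at the default
   resolution) and removes a baseline per spectrum by asymmetric least
   squares; no temporal averaging.
5. **ASLS baseline.**  Whittaker smoother with a second-difference penalty:
   minimise `Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)²` with `w = p` above the baseline and
   `1−p` below, iterated to weight convergence (defaults λ = 1e4,
   p = 0.001, ≤10 iterations; banded Cholesky solve).  λ = 1e4 gives a
   smoothing length of ~10 bins, well above the ~6-bin metabolite
   linewidth.  The λ→∞ limit is a straight line under the asymmetric
   weights, which the tests verify.

Cohort analyses average the per-scan spectrograms transient-wise; for the
GLM profile the baseline correction is applied to the cohort mean (the
analysis of participant-averaged data), and optionally per scan.

## Conventional block analysis

Metabolite levels are approximated by integrals of the baseline-corrected
real spectrum over fixed windows (lactate 1.24–1.40, aspartate 2.70–2.82,
glutamate 2.30–2.40, tNAA 1.95–2.07 ppm).  These *proxy* levels stand in
for full basis-set fitting (LCModel/ABfit-style), which is deliberately out
of scope; on synthetic data, where the underlying resonances are known, the
proxy integral tracks the simulated concentration changes to within a few
percent.  Block dynamics are labelled task/rest by the midpoint rule — a
dynamic is "task" iff its temporal midpoint falls inside the task window —
which for 15 × 100 s dynamics and a 180–660 s task yields 5 task and 10
rest points and hence the df = 13 of a pooled two-sample Student t-test.
Two cohort averaging schemes are computed: levels measured on the
cohort-mean spectrogram (scheme A) and per-scan levels averaged afterwards
(scheme B); random-phase artefacts cancel in scheme A but not in scheme B.

## Spectro-temporal GLM

Every frequency point of the (participant-averaged) transient-resolution
spectrogram is treated as an independent time course and fitted by ordinary
least squares against a design with an intercept, a 0/1 task boxcar
(optionally delayed by a lag, default 120 s when modelling slow metabolite
responses) and an optional nuisance regressor.  The nuisance regressor is
the temporally smoothed (51-transient centred moving average, our choice —
the span is not prescribed anywhere) integral of the 1.97–2.04 ppm region:
line broadening moves amplitude out of this narrow window around the tNAA
singlet, so the time course tracks lineshape drift and absorbs
drift-driven variance at all singlets.  Regressors other than the intercept
are demeaned; the task column keeps its 0/1 scaling so β_task is the
task-locked signal change in (tCr-normalised) spectrogram units.

Per point: `β̂ = (XᵀX)⁻¹Xᵀy`, `se` from `σ̂²(XᵀX)⁻¹` with `σ̂² = RSS/df`,
`t = β̂/se`, and two-sided Student-t p-values.  Columns fitted exactly
(RSS ≈ 0, e.g. noise-free synthetic input) are flagged and get NaN rather
than p = 0.  Family-wise control uses the Bonferroni threshold α/n over
the n retained frequency points (0.05/544 ≈ 9.2e-5 at the default
resolution); significance is strict (p *below* the threshold).  Manhattan
tables/plots show −log₁₀ p against ppm with the dashed threshold line.
Sidedness is not stated for the published threshold; two-sided tests are
used, the conservative choice.

## Quality control

* **Single-shot SNR**: real-part maximum within 2.01 ± 0.05 ppm (the tNAA
  singlet) divided by the standard deviation of the linearly detrended real
  part over 9.5–11.5 ppm, a signal-free region on the 4.65-centred axis
  (the noise window is our choice).  Scan summary = median over transients.
* **Linewidth**: FWHM of the tNAA peak with half-height crossings located
  by linear interpolation after removing a linear baseline across the
  search window.  The default ±0.15 ppm window keeps the Lorentzian-tail
  bias of this estimator below 1% for ~0.05 ppm Voigt lines (at ±0.1 ppm
  the bias reaches ~2.5%); per-dynamic values are smoothed by a 3-block
  centred moving average and reported as % change from the first point.
* **Difference spectrograms**: dynamic mean subtracted, 4 Hz Gaussian
  broadening (frequency-domain convolution), per-spectrum linear baseline —
  the standard visualisation of temporal variance such as scalp-lipid
  contamination between 1 and 1.5 ppm.
* **Exclusion**: a scan is flagged when the smoothed FWHM exceeds 0.07 ppm
  or degrades by more than 0.02 ppm from its first time point (strict
  inequalities; values exactly at a limit are retained).  Large
  transient-to-transient alignment jumps (>5 Hz) raise an *advisory*
  movement flag only, since movement screening is ultimately a visual call.

## Synthetic data generator

Each resonance contributes
`a(d)·exp(i2πft + iφ)·exp(−πLt − (πGt)²/(4 ln 2))`, i.e. a Voigt line whose
Lorentzian and Gaussian FWHM contributions are `L` and `G` in Hz.
Amplitudes are parameterised as isolated spectral peak heights relative to
the tCr singlet = 1.  The default table holds tNAA 2.01 (1.3), tCr
3.03/3.92 (1.0/0.65), tCho 3.22 (0.9), a lactate doublet 1.28/1.35 (0.05
each), glutamate 2.35/2.08/2.12 (0.45/0.25/0.25), aspartate 2.74/2.78
(0.12 each) and myo-inositol 3.55/3.59 (0.5/0.45); all lines use L = 4.0,
G = 3.2 Hz, giving a Voigt FWHM of ≈5.8 Hz = 0.047 ppm at 123.22 MHz.  The
lactate doublet is represented as two Lorentzian-Gaussian lines rather than
a J-coupled quantum simulation: the mass-univariate analysis operates at
the level of spectral features, not coupling evolution.

Dynamic responses are `constant`, `boxcar`, or `lagged_trapezoid` (linear
rise over `lag_s` after task onset, plateau, linear decay over `decay_s`
after offset; defaults 120 s each, reflecting the minutes-scale kinetics of
activation-driven metabolite changes).  Default effects: lactate +20%
(lagged), glutamate +2% (boxcar), aspartate −4% (lagged).

Confounds:

* **Scalp lipid artefact** — three broad Gaussian-damped lines at
  1.10/1.30/1.45 ppm (G = 25 Hz) sharing one uniform-random zero-order
  phase per scan.  The amplitude follows a smooth random waveform per scan
  (white noise smoothed on a 120 s timescale, zero-mean, normalised to unit
  maximum excursion): a time-*constant* artefact would vanish identically
  under dynamic-mean subtraction, whereas real lipid contamination
  fluctuates with subtle motion, which is exactly what difference
  spectrograms display.  The per-scan scale is phase-aware: it is chosen so
  the maximum |real part| of the phased lipid hump equals
  `lipid_amplitude_frac` × the tCr peak height, i.e. the stated artefact
  amplitude is what an analyst *observes* in the phased spectrum.  With 19
  scans and independent phases the artefact in the cohort mean falls by
  ≈√19, leaving a ~3.4% residual from a 15% input — the `1/√N` phasor law.
* **Linewidth drift** — a linear ramp multiplying both damping constants,
  reaching `1 + drift_fwhm_frac` at the final transient (default +20%,
  up to +40% in the worst observed scans).
* **Frequency/phase jitter** — per-transient Gaussian offsets (defaults
  1 Hz and 5°) emulating the instability the alignment stage corrects.
* **Noise** — i.i.d. complex Gaussian per FID point.  `calibrate_noise`
  inverts the analytic relation `spectral noise sd = σ·√n_points` to hit a
  target single-shot SNR (default 31) defined on the tNAA peak.

What the generator does **not** emulate: J-evolution and multiplet phase
distortions, macromolecule baselines, B₀-map-driven asymmetric lineshapes,
subject-specific metabolite profiles, or temporally correlated physiological
noise.  Passing tests therefore demonstrate the correctness and calibration
of the analysis chain under the stated confound model, not performance on
in-vivo data.

## Problem sizes and determinism

All stochastic stages take explicit seeds (`numpy` `SeedSequence` spawning
per scan), and identical seeds give bit-identical cohorts.  The test suite
exercises the full 19-scan × 750-transient geometry for the cohort-level
checks (artefact suppression, effect recovery, nuisance efficacy) and a
compressed 150-transient design (60/120/120 s) for unit-level checks; the
Monte-Carlo repetition counts (8–60 depending on the check) were sized to
keep each statistical assertion at least ~3 standard errors away from its
pass boundary.  `scripts/acceptance.py` recomputes the Bonferroni threshold
of the analysis window and the 19-scan lipid residual (50 master seeds)
from scratch.

## Known limitations

* Proxy integrals are not concentrations; overlap from neighbouring
  resonances biases absolute levels (relative task-locked changes are
  unbiased under the simulation model).
* Bonferroni control is conservative under the strong inter-bin correlation
  induced by lineshape and applied broadening; random-field or permutation
  approaches would be natural extensions.
* The ASLS parameters are exposed but not auto-tuned; very broad genuine
  signals (e.g. macromolecule humps) would be partially absorbed into the
  baseline.
* NIfTI-MRS support covers single-voxel, coil-combined data only.
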