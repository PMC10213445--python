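# Methods

## Scope and data model

The package analyses 3-day mouse EEG/EMG recordings sampled at 128 Hz
and scored into WAKE / NREM / REM in 10-s epochs. Sleep scoring itself
is upstream: hypnograms arrive complete, and the package only refines
them with the EMG muscle-tone override. Time is zeitgeber time (ZT,
hours after lights-on); under constant darkness the projected ZT labels
are retained, since the quantities extracted here are clock-driven
rather than light-driven.

## EMG amplitude and the wake override

The per-epoch EMG amplitude is log10 of the epoch's sample standard
deviation (population convention, n in the denominator). EMG amplitude
is strongly bimodal — high muscle tone awake, low in sleep — so a
threshold is found with Otsu's method: a 256-bin equal-width histogram
over [min, max] of the finite amplitudes, an exhaustive scan of all 255
class boundaries for maximal between-class variance, and the threshold
reported as the upper edge of the chosen bin so that a strict `>`
comparison reproduces the histogram split. Between-class variance is
exactly constant across empty histogram gaps; ties are broken by the
middle boundary of the maximal plateau, which places the threshold in
the center of the silent region between the two modes. Epochs strictly
above threshold are relabeled WAKE; the rule never converts an epoch to
sleep, is idempotent, and is monotone in the threshold. Zero-variance
epochs get a missing amplitude (never −inf), keep their label, and are
listed in a QC log.

## Spectral estimation

A 10-s epoch at 128 Hz has a native frequency resolution of exactly
0.1 Hz, so the 0–16 Hz spectrum (161 bins, both endpoints included) is
read directly off the DFT of the mean-removed epoch: rectangular
window, no detrending, no interpolation; inputs whose native resolution
does not tile the 0.1 Hz grid are rejected. One-sided power is scaled
so all native bins sum to n × epoch variance (Parseval); the absolute
scale cancels in every downstream statistic. The DC bin is stored but
is identically 0 after mean removal; it is flagged invalid in rhythm
extraction and dropped from phase-estimation features.

Hourly stage-conditioned spectra are plain means over the epochs of
each stage within each hour bin [h, h+1). A (stage, hour) cell with no
epochs is masked, propagated as missing everywhere downstream, and
never interpolated — interpolation would fabricate rhythm.

## Rhythm components

For each (stage, frequency) hourly series the power is mean-normalized,
`norm_i = (hourly_i − ave)/ave`, and the first 24-h Fourier harmonic is
taken over the T = 72 hourly points:

    COS = (2/T) Σ norm_i cos(2πiΔt/τ),  SIN likewise,  τ = 24 h, Δt = 1 h,

with amplitude A = √(COS²+SIN²) and peak time t_p = atan2(SIN, COS)/2π·24
wrapped to [0, 24). Over three full cycles the discrete harmonics are
orthogonal, so a pure 24-h cosine is recovered exactly. Missing hours
are excluded from both the mean and the sums with T replaced by the
non-missing count — unbiased under missing-at-random sampling.

**Time assignment.** The value of hour bin [i−1, i) is assigned time
iΔt (the 1-based index convention of the defining sums). Against a
continuous modulation this biases t_p by +0.5 h relative to bin-center
truth — visible in the ground-truth recovery tests (injected peak 18.0,
recovered ≈ 18.5) and cancelling exactly in young-vs-old peak *delays*.
A `time_assignment="bin-center"` switch is provided for sensitivity
analysis; the index convention remains the default.

**Cosinor.** Hourly stage amounts are fitted with
y = M + A·cos(2π(t−φ)/P) by Levenberg–Marquardt least squares (lmfit):
M initialized at the mean, A at half the range (constrained ≥ 0), φ
from the fixed-24-h harmonic estimator, P starting at 24 h and bounded
to [20, 28] h by default (the free-running-period window for mice). A
flat series, or a fit collapsing to zero amplitude, has an
unidentifiable phase and period and is flagged rather than reported.

**Circular statistics.** Peak times are compared with the
Mardia–Watson–Wheeler uniform-scores test: times mapped to angles
2πt/24, pooled and ranked (midranks for ties), uniform scores
β = 2πr/N, and W = 2(R₁²/n₁ + R₂²/n₂) from the group resultants. Both
the asymptotic χ² (2 df) p-value and a label-permutation p-value
(9999 permutations by default, seeded) are reported; which variant a
given study used is often unclear, and at n ≈ 20 per group the two
agree to ~0.02. Circular means use the resultant-vector angle and are
undefined (NaN) for antipodal/degenerate samples.

## Phase estimation

ZT is encoded on the unit circle, (x, y) = (cos 2πZT/24, sin 2πZT/24),
and two *independent single-output* regressors are fitted, one per
coordinate, on hourly spectral distributions normalized to unit sum
(160 non-DC bins per constituent spectrum). Input modes: one stage's
spectrum (NREM, REM, WAKE), the pooled hourly spectrum ignoring stages,
or the concatenation of all three stage spectra. The estimated time is
atan2(ŷ, x̂)/2π·24 — scale-free, so predictions are deliberately not
renormalized onto the circle. Five regressors are available at their
scikit-learn defaults (linear, ridge, k-nearest-neighbor, support
vector, random forest); the random forest is seeded and, being the only
stochastic one, is averaged over seeds 0…n_trials−1 (default 5) in
leave-one-mouse-out evaluation, while deterministic regressors run
once. Accuracy is mean cos(2π(estimated − ZT)/24): 1 for perfect
estimation, −1 for a constant 12-h error, 0 for a constant 6-h error.
Which regressor ranks best is a property of the data, not of the
implementation, and is reported rather than asserted.

Missing (hour, stage) cells: per-stage and pooled modes drop the
sample; the all-stages mode imputes the missing constituent with that
mouse's time-averaged normalized spectrum for the stage (flagged), so
sample counts stay comparable across modes without inventing rhythm.

**Phase-shift sign convention.** Cross-cohort comparisons report the
phase *lag* = circular(actual − estimated), wrapped to (−12, 12]; a
positive lag means the cohort's spectra resemble the reference cohort's
at an earlier time, i.e. a phase *delay*. A cohort with a 2-h injected
delay therefore reads as lag ≈ +2 h.

## The synthetic generator

The generator is the package's ground-truth instrument; its defaults
define the study conditions for all recovery tests.

- **Stage occupancy.** Hourly probability curves (WAKE
  0.55 + 0.25·cos(2π(h−18)/24), REM 0.08 + 0.04·cos(2π(h−6)/24), NREM
  the remainder) give a nocturnal animal: ~80% wake at mid-dark, ~58%
  NREM at mid-light. They are realized by a ZT-dependent 3-state Markov
  chain whose per-hour transition matrix is built from detailed-balance
  fluxes solving the target stationary occupancies at fixed mean bout
  durations (WAKE 60 s, NREM 100 s, REM 30 s — realistic fragmentation
  for mice; flux solutions driven negative by the occupancies are
  clamped to zero, slightly lengthening those bouts while preserving
  stationarity exactly). The chain mixes within minutes, so hourly
  occupancies match the profile to binomial error.
- **EEG.** Per-stage spectral templates on the analysis grid (NREM: a
  delta bump at ~2.5 Hz on a 1/f background; REM: theta peak at 7 Hz;
  WAKE: broad ~9 Hz component). Power at frequency f and epoch time t
  is template × (1 + a(f)·cos(2π(t−p(f))/24)); the default modulation
  maps peak NREM delta mid-dark (a = 0.3, p = 18 h at 4 Hz, low delta
  frequencies peaking in the light phase) and REM/WAKE components
  mid-light (p = 6 h), with a floor of a = 0.05 elsewhere. Epochs are
  synthesized by inverse FFT of the target one-sided magnitude spectrum
  with independent uniform random phases per epoch — the spectral
  *magnitudes* are deterministic, so the analysis grid matches the
  synthesis grid exactly and recovery tolerances are limited only by
  stage sampling and within-hour averaging of the modulation.
- **EMG.** White noise with per-epoch standard deviation drawn
  log-normally: log10-amplitude means 1.30 (WAKE), 0.50 (NREM), 0.35
  (REM), sd 0.15 — a cleanly bimodal distribution (wake vs. sleep
  separation ≈ 3.8 sd) as seen in nuchal EMG.
- **Aging.** A two-parameter transform: modulation amplitudes and
  occupancy-rhythm deviations multiplied by an attenuation factor
  (default 0.5) and all peaks/phases delayed by a common shift
  (default 2 h) — the attenuated-and-delayed phenotype of aged mice.
- **Seeding.** One root seed; per-mouse, per-purpose `SeedSequence`
  streams. Identical spec ⇒ bit-identical cohort; mice are mutually
  independent, and a cohort's first k mice coincide with the k-mouse
  cohort of the same seed.

**What the generator does not emulate:** real EEG morphology (spindles,
theta bursts, artifacts), cross-epoch signal continuity, epoch-to-epoch
power fluctuations beyond stage occupancy, light-masking of behavior,
and inter-individual variability of templates. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
signal model, not performance on real recordings — in particular the
near-ceiling phase-estimation accuracies on synthetic cohorts exceed
what real data support.

## Problem sizes and numerical choices

Recovery tests run on cohorts of 5–10 mice × 3 days (the package's
standard study size for synthetic validation); the Markov chain yields
~26k epochs per mouse and the FFT synthesis/analysis round-trip is
vectorized per hour. Degenerate inputs are handled explicitly: all-zero
spectra refuse normalization; zero-amplitude harmonics have undefined
peak time (NaN); antipodal circular means are NaN; Otsu requires two
distinct values; decoding the planar origin yields a missing time.
Tolerances asserted in tests derive from the model: exact (1e-9) where
discrete orthogonality applies, sampling-limited (±0.05 amplitude,
±1 h peak) for end-to-end recovery.

## Known limitations

- The first-harmonic extractor assumes a fixed 24-h period; free-running
  periods are the cosinor's job (and only for stage amounts).
- The MWW permutation test is exact only up to Monte-Carlo error; the χ²
  form is asymptotic and anticonservative for very small groups.
- The all-stages imputation of missing cells biases toward the mouse's
  mean spectrum in hours where a stage is absent; with strongly
  fragmented sleep this shrinks apparent rhythmicity.
- Stage-conditioned spectra are only as clean as the stage labels. The
  wake override misclassifies a small, time-constant fraction of sleep
  epochs, and because sleep *occupancy* is rhythmic, the fraction of
  such epochs inside each hourly WAKE cell varies with ZT — imprinting
  a weak occupancy-driven rhythm on the WAKE spectra even when the
  underlying spectral modulation is zero. Null-condition evaluations of
  purely spectral time information should therefore use truth/scored
  labels without the override (as the package's own null tests do).
- EDF input is not handled; signals are exchanged as epoch-aligned CSV.
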