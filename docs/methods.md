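# Methods

`mirebound` implements a time-domain analysis of the post-movement beta
rebound for discriminating motor execution (ME) from motor imagery (MI), and
a feature-based classification stack for ME-vs-MI and left-vs-right-hand MI.
This note documents the models, the defaults and why they were chosen, what
the synthetic generator does and does not emulate, and the numerical
decisions that matter.

## ERD/ERS

Event-related desynchronization/synchronization is the percentage change of
trial-averaged band power relative to a task-free reference interval:

    ERD/ERS_i = (A_i − R) / R × 100%

with `A_i` the average power of sample *i* over trials and `R` the average
power over the reference interval; negative values are ERD, positive ERS.
Band power is computed per trial by zero-phase band-pass filtering
(Butterworth order 4, forward–backward), squaring, and a moving-average
smoothing, then averaging over trials.

Defaults and rationale:

- **Band 13–40 Hz.** The beta range in which the rebound is observed.
- **Reference interval [−1.0, −0.1] s.** Pre-stimulus, task-free; the last
  100 ms are excluded as a guard against stimulus-locked smearing by the
  smoothing window.
- **Smoothing window 0.25 s.** Instantaneous band power from ~40 trials has
  a relative standard error near 15% per sample; a quarter-second moving
  average brings the ERD/ERS trace noise to a few percentage points, which
  the extrema-based follow-up statistic needs, while attenuating a 0.3 s-wide
  rebound peak by under 10%. A shorter window (0.125 s) leaves the
  difference-trace extrema too noisy for any excursion threshold to separate
  real from null cohorts.
- **Edge handling.** Band-pass filtering uses *even* (symmetric) signal
  extension. Odd extension flips the oscillation phase at the epoch
  boundary and cancels band power over the filter transient, producing a
  spurious ~50% "ERD" at the epoch edges.

Significance is a percentile bootstrap: trials are resampled with
replacement (default 1000 resamples), the full ERD/ERS statistic is
recomputed per resample, and a sample is flagged when the 95% interval
excludes zero. The per-trial smoothed power is computed once and reused
across resamples, so the bootstrap is exact for the statistic and cheap.

## Beta-rebound detection and the follow-up rule

A rebound event is a local maximum of an ERD/ERS trace inside the search
window (default 0–3 s post-stimulus) above a minimum amplitude (default
10% ERS), annotated with its latency, peak amplitude, and full width at
half the peak amplitude. The ME/MI single-trace vote classifies an event by
three thresholds (amplitude, latency, duration): low-amplitude, late, long
events vote MI; the majority of the three votes decides. Default thresholds
are the midpoints of the default synthetic condition profiles.

The **follow-up** decision works on the ME − MI difference trace at Cz: with
`t+` the time of the maximum and `t−` the time of the minimum inside the
search window, the pattern is present when both excursions reach
`min_magnitude` and `t+ < t−` (the ME rebound precedes the MI rebound).
`min_magnitude` defaults to 12%, calibrated so that null synthetic cohorts
(identical ME and MI profiles) produce false follow-ups in well under 10% of
paired 40-trial runs while real default-profile cohorts are detected in
over 95% (measured on 300 independent paired runs per condition). The rule
is monotone in `min_magnitude` by construction.

Summaries report, per subject or per motion, the percentage of pairs showing
the pattern, plus the mean and sample SD over keys.

## The synthetic generator

Each trial is `1/f`-shaped Gaussian background noise plus a sinusoidal
sensorimotor oscillation (carrier at the band center, per-trial frequency
jitter ±2 Hz, random phase per trial and channel) whose amplitude envelope
encodes the condition: an ERD plateau (smooth-edged box from 0.25 s to the
rebound onset) on the ERD channels and a Gaussian ERS bump (parameterized by
amplitude, latency, FWHM duration) on the rebound channels. Rebound peak
times get per-trial Gaussian jitter (SD 0.1 s).

Two calibrations make the profile parameters *observable*:

1. **Band-leakage compensation.** The broadband background contributes power
   to the analysis band; the oscillation modulation is scaled by
   `1 + band_fraction / snr²` (band_fraction computed exactly from the
   synthesis weights) so the measured trial-averaged ERD/ERS matches the
   configured percentages.
2. **Jitter-broadening compensation.** Latency jitter convolves the
   ensemble-average bump with the jitter distribution; per-trial amplitudes
   are scaled by `σ_jittered / σ_envelope` so the *ensemble* peak matches the
   configured amplitude.

Default condition profiles encode the qualitative ME/MI contrast: the MI
rebound has a quarter of the ME amplitude, peaks 0.2 s later (1.6 s vs
1.8 s, consistent with reported example peak times of 1.624 s and 1.818 s),
and lasts longer (1.0 s vs 0.3 s FWHM); the ME rebound spans Cz and its
fronto/centro-parietal neighbours while the MI rebound is confined to Cz;
left/right-hand MI profiles place a −50% ERD on the contralateral central
channel (C4 for left, C3 for right). Absolute amplitudes (ME 100%, MI 25%
ERS) and durations are package choices — only the ~25% amplitude ratio and
the latency contrast are externally anchored — set once so that the
documented detector operating characteristics (≥90% detection, ≤10% false
rate at 40 trials/condition and snr 1) hold with margin.

What the generator does **not** emulate: ocular/muscle artifacts, volume
conduction and channel cross-talk (channels carry independent noise),
non-stationary background spectra, inter-subject variability beyond seed
noise, and variable MI task duration. Passing tests therefore demonstrate
the pipeline's correctness and statistical behavior under the modeled
signal structure, not performance on recorded EEG.

**Seeding.** Identical seeds give bit-identical epochs. One practical
caveat found during calibration: numpy `Generator` streams seeded with
*adjacent* integers are weakly correlated (we measured ~0.06 correlation
between trial-averaged band-power traces), enough to bias paired-cohort
statistics. All cohort builders therefore derive per-condition seeds from a
single master stream rather than by incrementing.

## Features

- **Statistics (6/channel):** mean, SD, and mean absolute first and second
  differences of the raw and of the standardized signal. The six-feature
  set per channel is required by the documented matrix sizes; the mean is
  the standard companion of the five enumerated statistics.
- **Wavelet (3/channel):** db4 three-level DWT; from the level-3 detail
  coefficients `c`: RMS, energy `Σc²`, and Shannon entropy of `p = c²/Σc²`
  (`0·log 0 := 0`).
- **Band power (4 or 8/channel):** Welch PSD (1 s Hamming segments, 50%
  overlap), absolute band power (PSD integrated over the band) and relative
  power (band/total over 1–60 Hz) for alpha (8–12 Hz) and beta (13–40 Hz);
  the left-vs-right configuration additionally splits beta into low
  (13–20 Hz) and high (20–40 Hz) sub-bands, which is the decomposition
  consistent with the documented 24-column power block over three channels.
- **Sample entropy (2/channel on Cz/C3/C4):** m = 2; r = 1.0·SD on the raw
  epoch and r = 0.1·SD on the per-trial normalized band-power series (the
  single-trial analogue of ERD/ERS; the trial-averaged definition cannot
  produce per-trial features). Two counting conventions are implemented:
  the *literal* form (templates `i = 1..T−m+1`, strict Chebyshev `< r`,
  self-matches included, `(T−m+1)²`-type denominators) and the *canonical*
  estimator (both template lengths indexed to `T−m`, self-matches excluded,
  `≤ r`, `(T−m)(T−m−1)` denominator). Literal is the default; both are
  verified against a brute-force double-loop oracle. An infinite value (no
  length-3 matches) is imputed with the largest finite value the estimator
  can produce at that series length, keeping feature matrices finite.
- **CSP (2):** class-average trace-normalized covariances, generalized
  eigendecomposition, filters sorted by eigenvalue, the first and last
  retained. Features are the literal normalized log variances
  `f_i = log var Y_i / Σ_k log var Y_k` (so `f₁ + f₂ = 1`); the conventional
  `log(var/Σvar)` form is available as `feature_mode="conventional"`. The
  literal normalization makes the two features affinely dependent; it is
  kept as the default because the documented feature counts include both.

Task assemblies: `me_vs_mi` = 13 columns on Cz (6 + 3 + 4); `left_vs_right`
= 59 columns on Cz/C3/C4 (18 + 9 + 24 + 6 + 2). In the left/right assembly
CSP is fitted on the full epoch set (the documented matrix is a single
trials × 59 table); users running cross-validation on CSP-bearing matrices
should be aware of that transductive step — selection and standardization,
by contrast, are refit inside every training fold.

Features are computed on the post-stimulus reactive window (default
0.25–2.75 s); the ERD/ERS series feeding sample entropy is normalized
against the pre-stimulus reference of the full epoch before cropping.

## Sparse logistic regression

All four variants standardize features internally and never penalize the
intercept.

- **SLR-LAP / SLR-VAR (ARD):** Bayesian logistic regression with a per-weight
  Gaussian prior precision ("relevance"). The posterior is approximated by
  a Laplace step (Newton MAP + local Gaussian) or by the Jaakkola–Jordan
  variational bound. Relevance precisions are re-estimated from the
  marginal-likelihood sparsity/quality factors (`s_j`, `q_j`): a feature
  with `q² ≤ s` has its evidence maximized at infinite precision and is
  pruned; the others take the fixed point `α = s²/(q² − s)`. Precisions
  above 1e8 are hard-pruned during iteration. The final *selection* keeps a
  surviving feature only when its evidence gain `½(z² − 1 − ln z²)`,
  `z² = q²/s`, exceeds a Bayes factor of 3 (moderate support): with
  abundant data relative to the feature count, the bare fixed point retains
  any feature hovering near one posterior SD, which defeats the purpose of
  selection.
- **L1-SLR-LAP / L1-SLR-COMP:** MAP under a Laplace (double-exponential)
  prior, i.e. L1-penalized logistic regression — solved globally
  (liblinear) or by cyclic coordinate descent with the ¼-curvature bound.
  The penalty is chosen by internal repeated stratified 5-fold CV (3
  repeats) with a one-standard-error rule whose sparsest candidate is the
  empty majority-vote model; the SE uses the number of distinct splits as
  the effective sample size. Exactly collinear active columns are
  canonicalized by concentrating the weight on the first of the pair (the
  L1 optimum is non-unique along such spans and coordinate solvers
  otherwise report arbitrary splits).

Convergence: relevance log-changes below 1e-4 (ARD) or coordinate steps
below 1e-5 (CD), capped at 500 outer iterations; weights exceeding 1e3 in
magnitude (separable data) are capped with `converged=False`.

## Classification

The classifier is a soft-margin SVM (RBF, C = 1, gamma scaled) behind a
standardization step, both refit per training fold of a stratified k-fold
(default k = 10). An optional nested grid search covers linear/RBF/
polynomial kernels and their penalty/scale parameters. Reported quantities:
per-fold accuracies, pooled accuracy, fold-averaged confusion matrix,
per-class recall, and — when selection is active — the median per-fold
count of surviving features ("features left").

## Known limitations

- The follow-up rule uses global extrema of the difference trace; multi-peak
  traces are adjudicated implicitly by the extremum, and an alternative
  independent-peak comparison is not the default.
- CSP in the task assembly is transductive (see above).
- Bootstrap significance is computed but not required for counting a
  rebound toward the follow-up decision.
- The ARD evidence threshold (Bayes factor 3) and the L1 one-SE rule are
  selection conventions; different conventions change "features left"
  without much affecting accuracy.
- Group-level synthetic cohorts share one profile per condition; real
  cohorts have subject-specific rebound morphology.
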