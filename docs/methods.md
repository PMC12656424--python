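# Methods

This package implements a non-invasive swallowing-assessment pipeline for
Parkinson's disease (PD) screening: 32-channel submental high-density surface
EMG (HD-sEMG, 4x8 grid, 2048 Hz) plus a triaxial laryngeal accelerometer
(1024 Hz) per swallow trial, processed into a per-trial feature vector and a
subject-wise PD-vs-control classification.  The clinical dataset behind the
study design is private, so a synthetic-recording generator is a first-class
component: it defines the conditions under which every downstream stage is
exercised and tested.

## Signal model and preprocessing

sEMG is notch-filtered at 50 Hz (second-order IIR, quality factor Q = 30 — a
standard narrow mains notch that preserves adjacent EMG content) and band-pass
filtered 1-400 Hz with a 4th-order Butterworth; accelerometer axes are
band-pass filtered 0.1-5 Hz (4th-order Butterworth).  All filters are applied
forward-backward, so the net phase response is zero and the effective
magnitude order doubles.  The notch precedes the band-pass; the order is a
fixed convention (the two stages nearly commute for these bands).  Edge
transients are suppressed by reflective ("even") padding of up to 1 s before
the bidirectional pass.  Filtering contracts are tested directly: >= 95 %
attenuation of a 50-Hz tone, <= 5 % passband loss at 100 Hz, zero-lag
cross-correlation for in-band tones, and DC rejection by the accelerometer
filter.

Three normalizations are provided: z-score (sample SD, ddof = 1), robust
(median/IQR, with IQR = 75th - 25th percentile under linear interpolation —
stated because quantile conventions differ), and min-max onto [0, 1].

## Swallow detection and epoching

Both streams are scanned with 0.5-s windows stepped by 0.2 s (0.3-s overlap)
on a shared continuous-time clock, so the two sampling rates need no
resampling.  Per window the pipeline takes the RMS of the grid-averaged sEMG
and of the accelerometer vector magnitude; each trace is min-max normalized
over the trial (making the fusion invariant to per-modality gain and offset),
and the fused score is their unweighted mean.  This is the simplest member of
the "energy features, fused" family; the per-modality weighting is exposed in
code.  Windows overlapping annotated intake or mastication intervals are
excluded (set to -inf) before taking the argmax; the earliest window wins
ties.  The analysis epoch is the 2-s segment centered on the peak
(t_peak - 1 s to t_peak + 1 s); if the window would overrun a trial boundary
it is shifted minimally to fit and the shift is recorded — this preserves
equal segment lengths without fabricating samples.

## Core descriptors

With sEMG_i the filtered signal at sample i and N the epoch length:

* RMS = sqrt(mean(sEMG_i^2)) and WL = sum |sEMG_{i+1} - sEMG_i|, computed per
  channel and averaged over the 32 channels;
* the asymmetry index AS = RMS(left-half channel average) - RMS(right-half
  channel average), signed; grid rows 1-2 are "left", rows 3-4 "right"
  (row-major channel = row*8 + col), with the mapping stored per recording so
  other montages remain configurable;
* spectral descriptors from the unnormalized FFT of the 32-channel average
  (FFT length = segment length, one-sided, restricted to the 1-400 Hz
  passband — out-of-band bins carry only filter leakage): PF = frequency of
  the spectral maximum (lowest frequency among ties; the frequency, not the
  magnitude, is the quantity of interest), AF = magnitude-weighted average
  frequency, TP = sum of squared magnitudes with no extra normalization, so
  TP is comparable across equal-length segments.

## The 50-feature registry

The extended characterization is a frozen, versioned registry of exactly 50
named features; the mRMR stage's 15 retained features all resolve to registry
entries.  Conventions:

* Time-domain features are computed on each channel after per-channel min-max
  normalization (reducing inter-subject gain differences from skin
  conductivity or electrode placement); frequency-domain features on the
  non-normalized channels; every feature is computed per channel and averaged
  over the 32 channels.
* A min-max-normalized signal lives in [0, 1] and never crosses literal zero,
  so zero crossings and peak amplitude are taken about the channel mean
  (threshold 0, strict sign change).  Slope-sign changes use strict sign
  changes of the first difference.
* Central moments are population moments; kurtosis is Pearson m4/m2^2.
  "Difference in moments (4th - 2nd)" is m4 - m2 of the amplitude
  distribution.  The MAV slope splits the epoch into 8 equal segments and
  averages successive MAV differences.
* Hjorth mobility is reported in rad/s (fs * sqrt(var(diff x)/var(x)));
  complexity is the dimensionless mobility ratio.
* Sample and fuzzy entropy use m = 2, r = 0.2 x SD; fuzzy entropy uses
  exponential membership with gradient n = 2 and baseline-removed templates.
  Both run on the channel subsampled to <= 256 Hz by plain stride
  (factor round(fs/256)): O(N^2) template matching at 2048 Hz across 32
  channels per epoch is not tractable, and the subsampling is part of the
  frozen feature definition (the aliasing this introduces is immaterial for a
  fixed, documented complexity measure).  SVD entropy embeds with dimension
  10, delay 1, Shannon entropy (nats) of normalized singular values.
* AR coefficients are order-4 Yule-Walker prediction coefficients from the
  biased autocorrelation (4 registry slots).
* Spectral entropy is the Shannon entropy of the normalized power spectrum in
  1-400 Hz; Renyi entropy is order 2 on the same distribution.  The frequency
  ratio is power(1-60 Hz)/power(60-400 Hz); the mean power ratio is mean
  power(1-200 Hz)/mean power(200-400 Hz); spectral concentration is the
  fraction of band power within +/- 20 Hz of the mean frequency.
* The registry's "mean frequency" is the standard power-weighted MNF (and the
  mean/median-frequency ratio uses it); the magnitude-weighted AF above is
  kept separate as a core descriptor.  Median frequency is the cumulative-
  power midpoint bin.
* Time-frequency features use a short-time transform with 0.25-s Hann frames
  and 50 % overlap, band-restricted: mean frame energy, signal stability
  (variance of frame-wise RMS of the raw frames), instantaneous median/mean
  frequency (frame means), and the variance of the frame-wise central
  frequency.
* "Multiplied power and peak amplitude" is TP x max|x| of the raw channel.

Two registry slots are completion choices not pinned by the named feature
families (median absolute value and crest factor); they are ordinary sEMG
amplitude descriptors and are flagged here for transparency.  Every registry
feature and every core descriptor is tested against an independent
brute-force implementation (direct DFT matrix, explicit Toeplitz solve,
Gram-matrix singular values, explicit frame loops) at 1e-8 relative
tolerance on random 2-s epochs.

## Correlation screen

Pearson's r with the two-sided p-value from t = r sqrt((n-2)/(1-r^2)) on
n - 2 degrees of freedom, computed on trial-averaged per-subject feature
values per task.  Disease scores (MDS-UPDRS III, axial subscore, disease
duration) pair over PD subjects only; age and SDQ over all subjects.  Tests
are reported at per-test alpha = 0.05 with no multiple-testing correction by
default (matching the screening design); a Benjamini-Hochberg option exists.
The screen's type-I behaviour is verified by simulation (empirical rate in
[0.03, 0.07] under the null).

## Reduction

Features are z-scored (sample SD) so no family dominates by numeric range;
the scaler is an object reusable on held-out rows.  mRMR uses the canonical
difference (MID) form: greedily add the feature maximizing
MI(feature; group) - mean MI(feature; selected), with mutual information
estimated on equal-frequency 4-bin discretizations; the quotient form is
available via an option.  Ties break lexicographically by feature name, so
selection is deterministic and invariant to column order.  PCA components
come from the covariance eigenstructure (full SVD) with a fixed sign
convention (largest-magnitude loading positive); projections onto the
PC1-PC2, PC1-PC3 and PC2-PC3 planes are selectable.

Which rows enter mRMR/PCA was an open design point; the default is per-trial
rows pooled across the three tasks for the classification path (matching the
combined-task evaluation) and per-task rows for projection plots.

## Classification

Two regimes are deliberately separated.  The *visualization* regime trains an
RBF-SVM on all rows of one 2-D PCA plane and reports training-set metrics —
overfit by design, for boundary plots only.  The *evaluation* regime is
balanced subject-wise cross-validation: each random assignment partitions
subjects into floor(min(n_PD, n_HC)/2) folds of exactly 2 PD + 2 HC; with 15
PD and 7 HC this yields 3 folds and leaves 9 PD + 1 HC as training-only
subjects in every split (an exact 2+2 partition of an odd control count is
impossible; training-only leftovers are this package's resolution).  Per
fold, the scaler and a 3-component PCA are refitted on training rows only (no
test leakage, unlike the visualization regime — the difference is
intentional and explicit), test trials are projected onto PC1 and PC3, and an
RBF-SVM with inverse-class-frequency sample weights classifies them.  Test
predictions are pooled per seed before computing accuracy, precision, recall,
F1 and Cohen's kappa (kappa = (p_o - p_e)/(1 - p_e), marginal-product
expectation; defined as 0 when p_e = 1, e.g. single-class predictions).
Metrics with zero denominators are reported as not-computable, never as 0.
The sample unit is one swallow trial labelled with its subject's group; a
majority-vote subject-level view is available as an extra.  SVM
hyperparameters are unstated upstream; the defaults are C = 1 and
gamma = 1/(d var) ("scale"), exposed in the function signatures.

## Synthetic data: what it emulates and what it does not

Each trial is per-channel Gaussian noise (the instrumentation floor) plus a
swallow burst: white noise band-shaped by a zero-phase Butterworth band-pass
(giving direct control of spectral center and bandwidth for
parameter-recovery tests), enveloped by a Tukey (Hann-shaped
rise-plateau-fall) window of configurable duration, shared across channels
with left/right gains fixing the configured left/right RMS ratio.  The
accelerometer gets a biphasic low-frequency bump (one sine cycle under a Hann
window, ~1.25 Hz for the default 0.8-s duration) centered on the swallow,
dominant on the superior-inferior axis, plus noise.  Solid-bolus trials
prepend an irregular 1.5-Hz train of short (0.2 s) lower-amplitude bursts
between the annotated mastication start/end, stress-testing the detector's
exclusion logic.  Ground-truth swallow times are recorded as annotations.

Default group parameters: controls — burst 0.15 mV RMS, 1.0 s, centered at
120 Hz with 40 Hz bandwidth, symmetric (ratio 1.0), noise floor 0.01 mV,
accelerometer bump 0.05 g over 0.8 s; patients — half the burst amplitude,
spectral center 30 Hz lower, asymmetry ratio 1.2, otherwise equal.  These
inject group structure only through amplitude, spectral content and
asymmetry — the knobs that map one-to-one onto the feature families the
analysis screens (RMS/WL, PF/AF/TP, AS).  Amplitudes are in the range of
submental surface recordings; the clinical covariates are drawn from the
cohort table statistics (ages Normal(69.5, 7.5) PD / Normal(67, 4.8) HC
truncated to [50, 90]; scores uniform over the table ranges) and are
independent of the signals by construction.

The generator does not model motor-unit physiology, electrode-skin artifacts,
channel faults, swallow-to-swallow timing variability within a trial
(exactly one swallow per trial), or any true coupling between clinical
scores and signal characteristics.  Passing tests therefore demonstrate that
the pipeline recovers planted effects of the modelled kinds under realistic
noise — not that the classifier's clinical performance transfers to real
recordings.

## Problem sizes and numerical choices

The test suite exercises reduced cohorts (8 PD + 6 HC, 3 tasks, 2 trials,
8-s trials) for cross-validation calibration/power, 50 trials for detection
recovery, and 100 random epochs for oracle equivalence; the acceptance
script runs the full study conditions (15 PD + 7 HC, 3 tasks x 3 trials,
12-s trials, 500 CV fold seeds).  All randomness flows from explicit seeds
(numpy SeedSequence keyed by seed, subject, task and trial), so every
recording, cohort, fold assignment and report is exactly reproducible.
Degenerate inputs raise typed errors naming the offending quantity (constant
signals for normalization/entropy, all-zero spectra, constant feature
columns, all-excluded detection windows, single-class training sets).

## Known limitations

* The mastication annotations are simulator ground truth; with real data they
  must come from an external source (the upstream protocol used video).
* mRMR selection in the evaluation regime is fitted once on the full feature
  table (only the scaler/PCA/SVM are refitted per fold), mirroring the
  upstream protocol; selection-level optimism is therefore possible on small
  cohorts and is quantified by the null-cohort calibration test.
* The detector localizes exactly one swallow per trial; multi-swallow
  segmentation is out of scope.
* Feature values at sampling rates below ~800 Hz are undefined for the
  high-band ratios (no bins in 200-400 Hz); the registry assumes the study's
  2048-Hz acquisition (tests use >= 1024 Hz).
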