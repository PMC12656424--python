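# swallowsense

Non-invasive assessment of swallowing from wearable sensors, aimed at early
screening of subclinical dysphagia in Parkinson's disease (PD).  The input
per swallow trial is a 32-channel submental high-density surface EMG grid
(4x8 electrodes, 2048 Hz) synchronized with a triaxial accelerometer on the
thyroid cartilage (1024 Hz); the cohort design is 15 PD patients and 7
age-matched healthy controls (HC) performing three bolus tasks — water (WT),
gelled water (GT), solid bread (ST) — three trials each.  The package is for
biomedical-signal researchers who want a tested, reproducible version of
this analysis; because the clinical recordings are not public, an annotated
synthetic-recording generator with the same structure is part of the
package, and every stage is validated against it.

## Pipeline

1. **Preprocessing** — 50-Hz notch (Q = 30) + 1-400 Hz 4th-order Butterworth
   on sEMG, 0.1-5 Hz on the accelerometer, all zero-phase (forward-backward).
2. **Swallow detection** — 0.5-s windows stepped by 0.2 s on a shared clock;
   per-window RMS of the grid-averaged sEMG and of the accelerometer
   magnitude, each min-max normalized per trial and fused by their mean;
   the swallow peak is the argmax window center, with annotated
   intake/mastication windows excluded; the analysis epoch is the 2-s
   segment centered on the peak.
3. **Features** — core descriptors per epoch

       RMS  = sqrt( (1/N) sum_i sEMG_i^2 )
       WL   = sum_i |sEMG_{i+1} - sEMG_i|
       AS   = RMS_left - RMS_right              (grid-half averages)
       PF   = argmax_f |X(f)|,  AF = sum f|X(f)| / sum |X(f)|
       TP   = sum |X(f)|^2      over 1-400 Hz, FFT length = epoch length

   plus a frozen registry of exactly 50 time, frequency and time-frequency
   features (Hjorth parameters, sample/fuzzy/SVD/spectral/Renyi entropies,
   AR coefficients, band ratios, short-time descriptors, ...), each computed
   per channel and averaged over the 32 channels.  See `docs/methods.md`
   for every definition and parameter.
4. **Correlation screen** — Pearson r (two-sided p, t on n-2 df) between
   trial-averaged features and clinical covariates (MDS-UPDRS III, axial
   score, SDQ, age, disease duration), per task.
5. **Reduction** — z-scoring, mRMR (difference form, 4-bin equal-frequency
   mutual information) selecting 15 features, PCA with a fixed sign
   convention.
6. **Classification** — RBF-SVM with inverse-class-frequency weights on the
   PC1-PC3 projection, evaluated by balanced subject-wise cross-validation:
   folds of exactly 2 PD + 2 HC subjects, scaler/PCA refitted per training
   split, test predictions pooled per random fold assignment, repeated over
   500 assignments (accuracy, precision, recall, F1, Cohen's kappa,
   mean +/- SD and best seed).

The per-subject clinical tables of the study cohort (demographics, MDS-UPDRS
III, axial score, SDQ, LEDD) ship as packaged CSV fixtures
(`swallowsense.load_clinical()`).

## Worked example

The `analysis/` drivers run the whole study on the synthetic cohort at the
study conditions (fixed seed, deterministic).  Running them in order:

```sh
python analysis/01_simulate.py   # cohort + clinical table
python analysis/02_detect.py     # swallow detection per trial
python analysis/03_features.py   # 50-feature table (the slow step, ~2 min)
python analysis/04_correlate.py  # clinical-score screen
python analysis/05_reduce.py     # mRMR + PCA
python analysis/06_classify.py   # subject-wise CV
```

prints, among other things:

```
198 trials; detection error median 54 ms, 95th pct 101 ms
within 0.25 s of ground truth: 100.0%

group means (channel-averaged):
         rms  median_frequency  total_power
HC    0.5101             119.3    9.451e+04
PD    0.5103             89.71    2.401e+04

75 computable correlations; 2 flagged at alpha = 0.05 (2.7% ~ the type-I
rate expected when covariates are independent of the signal)

between-group silhouette, PC1-PC3 space: all features 0.600 -> mRMR-15 0.880

balanced subject-wise CV, 500 fold assignments, PC1-PC3, pooled tasks:
   metric  mean    sd  best
 accuracy 1.000 0.000 1.000
    kappa 1.000 0.000 1.000
```

Reading the numbers: the detector recovers every planted swallow to within a
quarter window; the patient group's lower spectral center (median frequency
90 vs 119 Hz) and weaker burst (total power 2.4e4 vs 9.5e4) are the injected
group effects, while the min-max-normalized time features (rms ~0.51 both
groups) are amplitude-invariant by design; the clinical covariates are
independent of the signals by construction, so the screen flags ~5% of tests
as expected under the null; and feature selection nearly doubles the
between-group silhouette before classification.  The ceiling CV metrics are
a property of the generator's deliberately strong default group separation,
not a clinical claim — the synthetic effect sizes are documented conditions,
not estimates of the clinical ones.

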