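# Methods

## The detection problem

The pipeline classifies 60-second epochs of beat-interval (R-R) data as
resting baseline (`BL`) or acute cold-pressor pain (`CPT`). The
physiological premises are (i) acute pain raises heart rate (sympathetic
activation) and (ii) suppresses respiratory sinus arrhythmia and other
beat-to-beat variability (vagal withdrawal). Raw HRV features are
dominated by inter-individual differences, so each classifier input is a
*baseline-normalized pair*: the element-wise absolute difference between
two of a subject's epoch feature vectors. A BL/BL pair measures how much
two resting epochs of the same person differ (label `BL`); a BL/CPT pair
measures the departure of a pain epoch from that person's rest (`CPT`).

## Synthetic cohort model

Beat interval *n* of a segment is

    I_n = 60000/HR + A_rsa · sin(2π f_resp t_n) + A_lf · sin(2π f_lf t_n + φ) + ε_n

with `t_n` the cumulative beat time, `φ` a seeded uniform phase,
`ε_n ~ N(0, σ²)`. Pain adds a subject-specific HR delta and multiplies
`A_rsa` by `pain_rsa_scale < 1`. This additive-modulation model (rather
than integral-pulse-frequency modulation) was chosen because every
downstream feature target is then analytically predictable: the interval
periodogram must peak at `f_resp`, the EDR stage must read back
`60·f_resp` breaths/min, and RMSSD must shrink with `A_rsa`.

Defaults describe the emulated study design: 41 subjects, 5-min baseline,
up-to-3-min cold pressor, with a 12/41 chance of stopping the immersion
early (early durations from a truncated normal, mean 1.34 min, SD
0.44 min, bounded to [1, 3] min). Physiological effect sizes are not
reported quantities anywhere we could source them for this paradigm, so
the defaults are the package's own choices of a realistic moderate
responder cohort: baseline HR 70 ± 8 bpm across subjects, pain delta
15 ± 4 bpm, RSA amplitude 40 ms at 0.25 Hz halved under pain, Mayer-wave
component 25 ms at 0.1 Hz, 20 ms white jitter. Per-subject seeds are
`seed + index`; beats are laid down until the nominal duration is
covered, so a 5-min record yields exactly five epochs. Any interval
falling below 300 ms raises an error rather than being clamped — such a
draw means the parameters are physiologically impossible, and silent
truncation would bias variability features.

What the generator does **not** emulate: ectopic beats and arrhythmia,
motion artifacts, non-stationary drift within a segment, realistic PQRST
morphology (the synthetic ECG is a Gaussian QRS template train for
detector validation only), and respiratory-rate changes under pain.
Passing tests therefore demonstrate internal correctness and sensitivity
under the stated generative assumptions, not field performance on noisy
ambulatory recordings.

## Signal ingestion

R peaks: 5–15 Hz band-pass → derivative → squaring → 150-ms moving-window
integration → threshold at 20 % of the integrated maximum with a 200 ms
refractory period, refined to the band-passed local maximum (±100 ms).
Intervals outside 300–2000 ms are rejected and counted, never
interpolated. Epochs are half-open windows `[k·60 s, (k+1)·60 s)`; an
interval belongs to the epoch containing its terminating beat; trailing
partial windows are discarded; epochs with fewer than 20 intervals are
dropped and logged (frequency and Poincaré estimates degenerate below
that).

## Feature conventions

* SDNN, SDSD, HR-SD and respiration-SD use the sample convention (n−1).
* RMSSD is the uncentred root mean square of successive differences.
* Poincaré SD1 is defined through the uncentred second moment of
  `(y−x)/√2`, which makes `SD1 = RMSSD/√2` an exact identity (tested to
  1e-9); SD2 is the centred population SD of `(x+y)/√2`. The more common
  centred-SD1 convention differs by the mean successive difference, which
  is O(1/n) for stationary data.
* NN50/NN20 count absolute successive differences above 50/20 ms;
  pNN50/pNN20 divide by the number of successive differences.
* Spectral analysis resamples the tachogram at 8 Hz — not the 4 Hz used
  by the respiration stage — because the VHF band extends to 3 Hz and
  needs Nyquist ≥ 3 Hz. The PSD is a single rectangular-window
  epoch-length segment (Welch machinery, one segment): with a rectangular
  window the integrated PSD preserves the series variance (checked to
  ~10 % against band-total power), whereas a Hann taper on this strongly
  autocorrelated signal systematically under-weights edge samples and
  biases total power low by ~8 %. Band powers are trapezoidal integrals;
  relative powers are percentages of the four-band total and sum to 100
  by construction; log powers are natural logs.
* The VLF band spans at most three frequency bins of a 60-s segment; it
  is computed for completeness but is spectrally under-resolved at this
  epoch length.
* ECG-derived respiration: 4 Hz resampling, 4th-order Butterworth
  band-pass 0.2–0.8 Hz applied forward–backward (zero phase), breath
  peaks with ≥ 1.25 s separation (reciprocal of the upper band edge) and
  ≥ 5 ms prominence. The prominence floor rejects filter edge transients
  and interpolation harmonics of out-of-band rhythms (≲ 2 ms) while
  genuine in-band RSA retains tens of ms. Fewer than three breaths in an
  epoch yields NaN sentinels; respiration is the only family allowed to
  be missing in an assembled vector (plus log powers of a degenerate
  constant epoch).

## Pairing and classification

Two pairing strategies: `all_pairs` (default; every unordered BL–BL pair
and every BL–CPT pair) and `mean_baseline_reference` (each epoch against
the subject's mean baseline vector). All-pairs inflates the sample —
C(5,2)=10 BL and up to 5·3=15 CPT observations per subject — and induces
class imbalance, which is left as-is (no reweighting). Observations from
different subjects are never mixed.

The per-fold model is StandardScaler → PCA (components retaining 95 % of
training variance; full SVD) → logistic regression (L2, C = 1, lbfgs,
max 1000 iterations, 0.5 threshold). Leave-one-subject-out
cross-validation keeps every observation of the held-out subject out of
scaler, PCA and classifier fitting; held-out predictions are pooled
across folds before computing per-class precision, recall, F1 and
support (rounding to 3 decimals happens only at report rendering).
Rows whose active feature set contains a NaN sentinel are dropped with a
logged count before folding — so a missing respiration value removes the
pair from the 46-feature laboratory model but not from the 18-feature
field model.

Under a per-subject label shuffle the classifier drifts toward the
majority class, so null accuracy approaches the majority rate (~0.6 with
the default pairing imbalance) rather than exactly 0.5; this is a
property of pooled accuracy under class imbalance, not leakage, and is
bounded in tests.

## Permutation importance

Importance of a feature is `score(baseline) − score(permuted)` on the
held-out fold, where the feature's column is shuffled *before* scaling
and projection (so attribution stays with named input features despite
PCA mixing), averaged over `n_repeats` seeded shuffles (default 10).
The score is macro-F1 by default (configurable to accuracy). Single-class
held-out folds cannot be scored and are skipped with a warning.
Fold-wise values are summarised per feature by median, quartiles, mean,
SD and outlier count (beyond 1.5 IQR), ranked by median with a stable
sort.

## Problem sizes and determinism

The test suite and the acceptance script use the 41-subject reference
cohort (≈ 1000 paired observations) for classification checks and a
20-subject cohort for the importance-direction check with 5 permutation
repeats per fold; both complete in seconds on a single core. All
randomness flows from explicit integer seeds (numpy `default_rng`), the
PCA solver is deterministic full SVD, and file writers avoid timestamps,
so any run is reproducible byte-for-byte from its config and seed.

## Known limitations

* The generator's stationary sinusoid-plus-noise beats are easier to
  classify than real cold-pressor physiology; absolute F1 values on
  synthetic cohorts overstate field performance and should be read as
  pipeline-correctness measures, not clinical accuracy claims.
* No ectopic-beat correction or PPG-specific artifact handling.
* VLF features at 60-s epochs are under-resolved (above).
* The respiration stage assumes breathing stays within 0.2–0.8 Hz; slow
  (< 12 breaths/min) breathing is reported as missing, not estimated.
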