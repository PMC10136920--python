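# Methods

This note records the models, parameter choices and numerical decisions
behind apneaflow, and what the synthetic validation does and does not
show.

## Scope and pipeline

The package screens single-channel PPG (optionally with red/IR
channels or a precomputed SpO2 series) for sleep apnea.  The stages are
independent library functions; `diagnose()` composes them:
preprocessing → 60-s windowing → multiscale entropy + PRV features →
random-forest window classification → oximetry gating → event merging →
AHI and severity.  Distinguishing obstructive/central/hypopnea event
types, frequency-domain PRV indices and real-time streaming are out of
scope.

## Preprocessing

* **Baseline removal** subtracts a centered running median of window
  `round(2.5·N)` samples (odd-adjusted, reflect padding), N the
  sampling rate in Hz.  The median of a quasi-periodic pulse train over
  2.5 s tracks sub-0.5 Hz wander while ignoring beats.
* **Median denoising** is a centered running median.  The library
  default window is 2 s (`2·N` samples); the *screening pipeline*
  default is 0.05 s.  A 2-s median applied to a ~1 Hz pulse wave
  flattens the beats themselves, which would defeat peak detection and
  entropy analysis, so the pipeline treats the step as impulse
  rejection and keeps the window an order of magnitude below the pulse
  period.  Both are configurable (`denoise_window_s`).
* **Lowpass**: Chebyshev type II (the stopband-ripple family; the
  stopband attenuation and passband ripple are the quantities specified,
  which this family meets by construction).  Given (order, cutoff,
  stopband attenuation), the stopband edge is located by bisection as
  the smallest frequency for which the response at the cutoff stays
  within the passband ripple; the returned design carries the edge and
  is verified on a dense grid, raising `FilterDesignError` otherwise.
  Defaults: order 10, cutoff 4.8 Hz, −60 dB, ≤ 1 dB ripple; an
  order-5/−40 dB variant matches embedded deployments.  Delay
  compensation drops the first M/2 output samples.  Because the true
  group delay at the pulse fundamental exceeds M/2, the pipeline
  additionally shifts detected peak indices by
  `round(group_delay(1 Hz) − M/2)` when mapping them back to the input
  clock; the residual misalignment is ~2 samples at 100 Hz.
* **Windowing**: 60-s windows, slide 1 s by default.  A window takes
  the apnea label of the minute covering ≥ 50 % of it (ties to the
  earlier minute) — labels are per minute, the usual annotation unit.

## Multiscale sample entropy

SampEn(m, r) = −ln(A/B) with B and A the numbers of template pairs
within Chebyshev tolerance r at lengths m and m+1, self-matches
excluded.  Conventions:

* m = 2, r = 0.2×SD, scales 1–15 (defaults; all configurable).  For the
  multiscale curve, r is referenced to the SD of the *original* window,
  the common MSE convention, so all scales share one absolute
  tolerance.
* Template counts use N−m templates at both lengths (the standard
  formulation), which makes SampEn of a constant series exactly 0 —
  the self-consistency a complexity measure should have.
* Counting is done with a k-d tree under the Chebyshev metric; the test
  suite checks exact (1e−10) agreement with an O(N²) brute-force oracle
  on dozens of random series.
* Improved coarse-graining slides a window of length τ by
  `max(1, round(τ/2))` (ties round up).  This keeps the tail whenever
  it completes a window and yields a series at least as long as the
  block-average one; the length property is checked exhaustively for
  L = 30…200, τ = 2…15.
* When no template pair matches (e.g. monotone series with steps far
  beyond r) the entropy is undefined: the entry is NaN, flagged via the
  vector's `undefined` mask, and imputed downstream with the training
  column median (the imputation mask is preserved).

## Peak detection

The quadratic-spline dyadic wavelet (smoothing filter
[1/8, 3/8, 3/8, 1/8], detail filter [2, −2]) is applied as an
undecimated à-trous cascade to level 3 (scale 2³).  The equivalent FIR
detail kernel is anti-symmetric; its center — found as the argmin of
the kernel's autoconvolution — gives the alignment shift, so the
+→− zero-crossing of a pulse's modulus-maxima pair lands on the pulse
peak (±1 sample on templates).  Edge padding is by sample repetition,
which keeps coefficients of constant signals identically zero.

Decisions along the chain:

* Thresholds are adaptive per 60-s chunk: thp = c·RMS(positive
  coefficients), thn = −c·RMS(negative), c = 1.5 by default.  This is
  scale-free (the wavelet is linear) and needs no calibration data.
* A candidate pair must have a monotone coefficient path between its
  members; small wiggles up to 5 % of the pair amplitude are tolerated
  so that noise does not veto genuine pairs.  Unpaired extrema are
  orphans and dropped.
* The refractory period is 200 ms, matching normal heart-rate limits.
* Missed-beat recovery: gaps > 1.5× the mean peak-to-peak interval are
  re-scanned strictly inside the gap (excluding both flanking 200-ms
  refractory zones) at 4/5 of the thresholds, in a single pass so
  termination is unconditional; the refractory rule is re-enforced on
  the merged train.

## PRV features and assembly

Nine time-domain statistics per window: PR (beats/min), mean/SD/median
of the PP intervals (ms), NN50 (strict "> 50 ms" on successive
differences), pNN50 = NN50 / number of differences (a fraction in
[0, 1]; multiply by 100 for percent), and mean/SD/median of the peak
amplitudes.  SDs use ddof = 1.  Windows with < 3 peaks are degenerate:
PR is kept, dispersion features are NaN → median-imputed with a mask.

The feature matrix is `[mse_s1 … mse_s15, pr, pp_mean_ms, sdnn_pp_ms,
pp_median_ms, nn50, pnn50, sdnn_aa, aa_mean, aa_median]` — a stable,
serialized column order.  Embedded feature selection fits a random
forest and keeps columns with impurity importance ≥ the mean importance
(threshold configurable; 0 keeps everything).  Selection, imputation
medians and the selection mask are fitted on training data only and
stored inside the model object.

## Classifier

Random forest, 500 trees, fixed seed (deterministic); SVM (RBF, with
standardization), k-NN (k = 5, standardized) and XGBoost comparators
behind the same `train_model`/`benchmark_models` interface.  Evaluation
uses a stratified 70/30 hold-out split.  Se/Sp/Acc come from the
confusion-matrix identities; ratios with zero denominators are NaN
rather than silently 0.

## Oximetry

Eq. SpO2 = C_HbO2/(C_HbO2+C_Hb)×100 defines saturation but is not
computable from light intensities; the package closes the gap with the
conventional empirical pulse-oximetry map SpO2 = 110 − 25·R, where R is
the per-second ratio of normalized pulsatile amplitudes
(AC via peak-to-peak, DC via mean; both channels per second).  The
calibration constants are configurable.  Seconds with vanishing AC or
non-positive DC are invalid (flagged, NaN).

Desaturation events are maximal runs below 90 %.  An event is
attributed to a signal artifact when ≥ 50 % of its seconds carry
quality flags — from the oximetry series itself and/or per-second PPG
proxies (pulsatile amplitude below 10 % of the record median, dropout,
non-finite samples), which stand in for probe loosening, motion and
weak perfusion.  Artifact events always produce a user-visible warning.

## Comprehensive judgment and AHI

With oximetry present, a PPG-positive window is confirmed only by
overlap with a *pathological* desaturation; overlap with only an
artifact-flagged drop rejects the window (with a warning); no overlap
rejects it as unconfirmed.  Without oximetry, PPG positives stand, and
the whole report is marked low-confidence.  Confirmed windows whose
spans overlap merge into events; an event needs ≥ 10 s of positive
coverage (apnea is a pause of roughly ten seconds or more).  AHI =
events / recording hours; severity: < 5 none, 5–15 mild, 15–30
moderate, > 30 severe (standard clinical cutoffs).

## Synthetic data: what it emulates, what it does not

Each beat is a two-Gaussian template (systolic lobe σ = 80 ms; dicrotic
lobe 30 % amplitude, 300 ms later, σ = 160 ms) placed at beat times with
Gaussian intervals N(60/HR, sd); default HR 70 bpm, sd 30 ms.  Inside
apnea episodes the interval sd is multiplied by 3 and the amplitude by
0.8 — a deliberately strong, *assumed* signature chosen so that apneic
windows are statistically separable; no generative physiological apnea
model is claimed.  Noise: 50 Hz power-line sine, EMG-like band-limited
noise above 10 Hz, and a low-pass-filtered random-walk baseline drift
below 0.5 Hz.  SpO2 sits at ~97.5 % (bounded to [96, 99]), falls toward
85 % with a 2-s lag and a 4-s time constant during episodes, and
recovers with a 10-s time constant; probe-loosening intervals drop
toward 75 % while the channel AC collapses to 5 % so quality heuristics
can flag them.  Dual-wavelength channels share the clean pulse shape
with the red AC scaled by R, making the ratio-of-ratios round trip
exact to well within 1 %.  The default sampling rate is 100 Hz — a
convention, not a device fact — and everything is seeded
(bit-identical regeneration).

Because the apnea signature is injected directly into the features the
classifier uses, perfect corpus metrics demonstrate that the *pipeline*
(detection → features → model → gating) is wired correctly and
leak-free — not that the method reaches any particular accuracy on
clinical recordings.  Real PPG differs in morphology variability,
motion artifacts, arrhythmias and far subtler apnea signatures; the
optional WFDB/EDF readers exist so users can run the identical pipeline
on polysomnography exports where those libraries are installed.

## Problem sizes

The shipped validation uses 16 training records of 6 minutes (≈ 80
windows at the 60-s training step), a one-hour screening recording with
five 60-s episodes analyzed at a 30-s step (118 windows), and a 10-min
artifact-only control.  These sizes were chosen to exercise every
code path — episode confirmation, artifact rejection, event merging —
while keeping a full run of the suite in the low minutes on one CPU.

## Known limitations

* The R→SpO2 calibration is the textbook linear map; real sensors need
  empirical per-device calibration (a quadratic map can be substituted
  via the `cal_a`/`cal_b` parameters).
* The artifact gate is binary per event with a fixed 50 % overlap rule;
  graded confidence is not modeled.
* Entropy at large scales on short windows can be undefined; imputation
  keeps the classifier total but discards that scale's information for
  the affected window.
* Event boundaries are window unions, so reported event spans are
  coarser than breath-level annotations.
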