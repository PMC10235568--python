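# Methods

This note documents the modelling choices behind `preictal`: the
prediction protocol, the synthetic data the package is validated on,
the numerical conventions, and the decisions taken where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The prediction model and its assumptions

The pipeline rests on the preictal-state assumption: a transitional
interval of duration `T_pre` before each seizure onset in which the EEG
background measurably departs from the interictal baseline. `T_pre` is
not observable and is treated as a hyper-parameter, grid-searched over
{30, 40, 50, 60} minutes.

All fitting is *quasi-prospective*: the first three chronological
seizures provide the training span; every fitted quantity — the
selected `T_pre`, per-feature means and SDs for standardization, class
weights or interictal subsamples, selected features, classifier
coefficients — is computed from that span only, and the API makes
leakage structurally impossible (test rows are split off before any
fitting operation sees them). Windows overlapping an ictal segment are
excluded from both training and the FPR denominator.

Two classifier families are provided. The logistic regression is
deterministic given its seed (used only by the feature-selection
forest) and its coefficients are directly interpretable. The SVM
ensemble addresses the instability of stochastic training steps by
voting: each of the 15 members redraws the interictal subsample (drawn
evenly from 10 equal time segments to cover slow nonstationarity) and
reruns feature selection with a member seed derived from the master
seed, so the whole ensemble is reproducible and member agreement is
itself a diagnostic (the acceptance script reports it).

## Alarm layer

Firing Power is the `τ`-window moving average of binary outputs,
`τ = T_pre / window`. During the first `τ − 1` windows the partial mean
over available windows is used and flagged (`warmup="full"`, dividing
by `τ`, is available; it makes the start of a record alarm-proof, which
is why it is not the default). The alarm threshold is 0.7; each alarm
opens a refractory span of `τ` windows; if the Firing Power is still at
or above threshold when the refractory span ends, a new alarm fires
immediately. Ictal windows never emit alarms.

An alarm at `t` predicts an onset at `t_sz` iff
`SPH ≤ t_sz − t ≤ SOP` with SPH = 10 min (the lead time a patient
needs to intervene) and `SOP = T_pre`. Each alarm credits at most one
seizure, the earliest eligible. A zero classifier margin is classified
preictal; this tie rule matters only for the counterfactual epsilon.

## Evaluation and statistics

* SS = predicted / total test seizures.
* FPR/h = false alarms / (interictal hours − refractory hours).
* TiW = total time with Firing Power at or above threshold.
* Surrogate test: each draw relocates every test onset uniformly
  within its own contiguous recording block, constrained so a full SOP
  fits before the relocated onset; the *fixed* alarms are re-scored;
  `p = (1 + #{SS_surr ≥ SS_obs}) / (n + 1)` (add-one keeps the test
  valid and conservative at any surrogate count; default n = 1000,
  α = 0.05). Blocks are the spans between consecutive ictal ends.
* Forecast mode drops the alarm machinery: a warning is any window
  with FP ≥ threshold, and a seizure counts as anticipated when its
  onset falls inside a warned window (no SPH — forecasting concerns
  risk states, not intervention lead time). The circadian baseline
  warns daily in ±30-min half-open intervals around each training
  onset's time of day, merged when overlapping.
* Patient-count statements use the upper-tail cumulative binomial test
  with an explicit null proportion `p0`; no default `p0` is assumed.

## Grid-search selection score

The deployed quantity is alarms, but a 3-fold leave-one-seizure-out
alarm chain yields an almost discrete score (one alarm opportunity per
fold): in practice neighbouring candidates tie and the shortest-wins
tie rule degenerates selection to 30 min. The default score is
therefore window-level: the held-out span's ROC AUC under the
candidate's labelling, standardized by its Mann–Whitney null standard
error, `z = (AUC − 0.5) / sqrt((n₁ + n₀ + 1) / (12 n₁ n₀))`. The
standardization matters: candidates label different numbers of windows
preictal, so raw AUCs fluctuate more for extreme durations and the
argmax would systematically prefer 30 or 60 min when no preictal
signal exists. With the standardized score, selection on null patients
is approximately uniform while a planted duration is recovered
reliably (both properties are measured in the acceptance suite). The
alarm-level score remains available (`metric="alarm"`).

## Synthetic data: what it emulates, what it does not

The generator mimics multi-day presurgical scalp monitoring: 256 Hz,
19-channel 10-20 montage, ≥ 4 seizures separated by ≥ 4 h 30 min
(enforced; shorter separations require an explicit override), ictal
segments of 60 s, circadian amplitude modulation, delta-boosted sleep
intervals from a configurable schedule, posterior 10 Hz alpha while
awake, and Poisson-scheduled 0.5–2 s broadband 20–100 Hz
muscle-artifact bursts (so the ablation experiment has a confound to
discriminate). The background is 1/f-coloured noise (β = 1), scaled to
~10 µV rms. All randomness descends from one master seed through named
substreams; identical configurations reproduce records bit-for-bit.

The preictal signature multiplies the power of designated bands
(default: 13–30 Hz plus the gamma bands) by a ramp over the `T_pre`
span. The ramp is linear in power from `(E+1)/2` to `(3E−1)/2` where
`E` is `effect_size`, so that (i) the time-averaged multiplier over
the span is exactly `E`, (ii) the multiplier steps up by `(E−1)/2` at
the preictal start, and (iii) `E = 1` is an exact null with both
endpoints at 1. The step in (ii) is deliberate: a signature that rises
continuously from the background level gives the preictal state no
identifiable beginning, making any preictal-duration search meaningless
— with a continuous-from-1 ramp the grid search measurably prefers
shorter durations regardless of the truth. For `E < 1` a constant
multiplier is used. No claim is made about the magnitude of real
preictal changes; `effect_size` is exposed precisely because that
magnitude is unknown.

What passing tests on this generator do **not** show: performance on
real EEG. The generator has no physiologic seizure morphology, no
inter-patient heterogeneity of preictal expression, no medication
tapering, no electrode artifacts beyond muscle bursts, and its
preictal signature is, by construction, present in every seizure.
Results on synthetic patients validate the *machinery* (metrics,
calibration, recovery, explanation logic), not clinical performance.

## Numerical conventions

* PSD: Hann-tapered single-segment periodogram on the mean-detrended
  5-s window; band powers are bin sums over `[f_low, f_high)`;
  relative powers divide by the power in 0.5 Hz to the top of the band
  table (128 Hz at full rate). The band table keeps printed protocol
  ranges; names are range-based (`band_8_13`, `band_13_30`) with both
  printed and conventional label aliases exposed, because the printed
  beta/alpha labels are swapped relative to convention.
* Band ratios: all unordered pairs `p_i / (p_j + 1e-12)`.
* Spectral edge: smallest frequency whose cumulative power reaches the
  requested fraction (default 0.5) of the 0.5–128 Hz total; the
  cumulative power at the edge is emitted alongside (the fraction is
  configurable, e.g. 0.9 for SEF90).
* Kurtosis is Pearson (Gaussian → 3); recorded in metadata.
* Decorrelation time uses the raw (not detrended) biased
  autocorrelation; windows dominated by an offset or drift saturate at
  the window length and are flagged.
* Wavelets: db4, 8 levels, periodization mode — the transform stays
  orthogonal, so detail + approximation energies equal signal energy
  (tested to 1e-6 relative); 5-s windows at 256 Hz (1280 = 2⁸·5
  samples) decompose exactly.
* Degenerate windows (constant signal) never produce NaN: affected
  features are zeroed and flagged per cell.
* Constant feature columns are dropped at standardization with a
  warning; forest-selection ties break by feature index; the logistic
  fit raises on non-convergence rather than warning.
* Counterfactual flips cross the decision boundary by a relative
  `1e-9` margin epsilon in both directions; ensemble counterfactuals
  use a signed grid scan plus bisection to 1e-6.

## Problem sizes

Tests and the acceptance script run the generator at reduced scale —
64–128 Hz, 1–2 channels, hours-long records with 80-min to 2.5-h
seizure separations — which preserves the generative model while
keeping the suite fast; the full clinical scale (256 Hz, 19 channels,
days) is exercised only for scheduling and column-count contracts.
Statistical checks use 100–1000 replicates as stated in each test; the
surrogate default of 1000 draws is reduced to 200 in the cohort
calibration runs.

## Known limitations

* The 5-s window grid anchors at the record start; onset times are not
  snapped to window boundaries, so preictal window counts can differ
  by one across seizures.
* The ensemble counterfactual search is per-feature; joint minimal
  perturbations are out of scope.
* The alarm-level grid-search score is retained for completeness but
  is statistically degenerate with only three training seizures (see
  above).
* EDF I/O is not provided; records use a float32 array + JSON sidecar
  container, annotations an ISO-8601 CSV.
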