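# Methods

`covertfnirs` detects covert volitional brain activity in block-design fNIRS
recordings: a subject is asked to (attempt to) move their tongue in timed
blocks, and the pipeline decides whether their cortex responded. This note
documents the model, the synthetic acquisition used to validate it, and the
numerical choices that were genuinely open.

## Acquisition model

Dual-wavelength (760 / 850 nm) continuous-wave intensities sampled at
10.17 Hz on an 8-source / 15-detector montage; 8 detectors are short-channel
detectors placed directly under each source (0.8 cm separation, sampling
scalp hemodynamics only), long channels have 3 cm separations. Sixteen long
channels cover four regions of interest — frontal, supplementary motor area
(SMA), tongue motor homunculus, parietal — with two channels per region per
hemisphere. Optode coordinates are schematic 10-10 positions; all downstream
logic keys on the per-channel ROI label, never on coordinates, except the
nearest-short-channel lookup, which measures distance from the long
channel's source optode (the short detectors sit under the sources, so each
long channel maps to its own source's short channel).

The task paradigm is 3 blocks of 8 repetitions of 15 s task / 15 s rest
(24 task epochs, epochs half-open `[onset, onset+duration)`), a 15 s lead-in
baseline and 30 s between blocks (both configurable; the block structure is
fixed by the paradigm, the gaps are package defaults).

## Synthetic data

Each simulated channel's chromophore series (µM) is a sum of:

- **Task response** (responder channels only): the task boxcar convolved
  with a canonical double-gamma HRF (gamma densities with modes 6 s and
  16 s, undershoot ratio 1/6, unit rate), peak-normalized, scaled by
  `hbo_amplitude` (default 0.5 µM); HbR gets −1/3 of the HbO amplitude.
  Default responders activate the tongue-motor ROI.
- **White measurement noise**, `noise_sd` (default 0.1 µM; HbR half that).
- **Polynomial drift** in normalized time (default a 0.4 µM linear term),
  with a random per-channel gain and sign.
- **A shared superficial systemic signal**: cardiac (1.2 Hz), respiratory
  (0.25 Hz) and Mayer (0.1 Hz) sinusoids with random phases plus a slow
  random walk, amplitude `superficial_amp` (default 0.5 µM). Short channels
  carry it at full amplitude, long channels at 50% (partial-volume scalp
  contamination); HbR carries 30% of the HbO superficial signal.
- **Motion artifacts** injected in optical-density space: Gaussian-bump
  spikes (< 1 s, ≥ 5× trace SD, default 0.5/min) and baseline steps that
  persist to the end of the record (default 0.1/min). Times and magnitudes
  are logged.

Concentrations are forward-converted per channel to OD via the modified
Beer-Lambert law and to intensity as `I(t) = exp(−OD(t))` (baseline 1 a.u.),
so the preprocessing chain inverts the generator exactly when noise is off.
A single integer seed fully determines a recording; cohort seeds derive from
`numpy.random.SeedSequence`.

What the generator does **not** emulate: 1/f physiological background,
arousal fluctuation, optode-coupling drift, spatially correlated noise
between neighbouring channels, or any photon-transport physics. Passing
tests therefore demonstrate the pipeline's statistical behaviour under a
stylized but structurally faithful acquisition, not clinical performance.

## Preprocessing

1. **OD conversion**: `OD = −ln(I / mean(I))` per channel × wavelength
   (natural log, consistent with the forward model).
2. **TDDR motion correction** per trace: split at 0.5 Hz; iteratively
   reweight the first differences of the low-frequency part with Tukey's
   biweight (c = 4.685, scale 1.4826·MAD, ≤ 50 iterations, tolerance 1e−8);
   re-integrate and re-add the high-frequency part. Spikes shorter than the
   0.5 Hz split survive as a zero-area high-frequency remainder that the
   subsequent low-pass removes; the two stages together attenuate 10×-SD
   spikes by ≳ 90%.
3. **MBLL**: `[ΔHbO; ΔHbR] = ε⁻¹ · OD_λ / (d · DPF_λ)` with extinction
   coefficients from the standard compiled hemoglobin absorption table
   (760 nm: 1486.59 / 3843.71; 850 nm: 2526.39 / 1798.64 cm⁻¹M⁻¹) and
   DPF 6.0 at both wavelengths (common adult default; both configurable).
4. **Filtering**: zero-phase 3rd-order Butterworth, default 0.01 Hz
   high-pass + 0.2 Hz low-pass with linear detrending; a cutoff of 0 turns
   that stage off. Generous `filtfilt` padding (10 cycles of the lowest
   cutoff) suppresses edge transients.
5. **Quality control** on raw intensity, before correction (both orderings
   are available): per-channel SNR = mean/SD (worse of the two wavelengths,
   threshold 8) and a cardiac spectral check (Welch with 20 s segments; a
   peak in 0.6–2.0 Hz must exceed 3× the 0.25–3 Hz median at both
   wavelengths). Recordings with a bad-channel fraction above 0.5 are
   excluded outright and yield an *indeterminate* (not negative) decision.
   The SNR definition, spectral band, peak factor and exclusion fraction
   are package choices; only the threshold of 8 is fixed by the protocol.

### TDDR amplitude transfer and matched regressors

TDDR multiplies any small superimposed low-frequency signal by the
derivative of its influence function, ≈ 0.8 across a wide range of noise
regimes — a systematic ~20% attenuation of evoked responses. The pipeline
therefore passes the task regressor through each channel's converged TDDR
weight operator (per wavelength, recombined through the MBLL inverse),
exactly as it band-filters the regressor with the same Butterworth the data
received. This removes the first-order bias; a second-order selection effect
(weights dip slightly more when background and task derivatives align)
leaves a residual ~13% shrinkage, so amplitude recovery is ≈ 0.87 of truth
rather than 1.0. Detection (a sign-and-significance decision) is unaffected.

## Detection

Per long channel and chromophore, a GLM of the filtered concentration series
on `[intercept, task, nuisance...]`:

- **GLM sampling rate**: the data and design are decimated after low-pass
  filtering to ≈ 2.5× the low-pass cutoff (e.g. 0.51 Hz for the 0.2 Hz
  default), so an AR(≤ 8) prewhitening filter spans ~16 s of the
  autocorrelation the low-pass induces.
- **Short-channel regression**: `nearest` (default; the short channel under
  the long channel's source), `all` (every good short channel), or `pca`
  (principal components to 90% cumulative variance). Zero good short
  channels falls back to no regression with a warning.
- **Prewhitening**: AR coefficients by Yule-Walker (MLE) on the OLS
  residuals; order selected in 0..8 by BIC (AIC is selectable; BIC keeps
  white-noise inputs at order 0 ≥ 90% of the time, which plain AIC does
  not), with a stationarity guard that reduces the order if characteristic
  roots touch the unit circle. The AR filter is applied to the response and
  every design column.
- **Robust fit**: IRLS with Tukey's biweight (c = 4.685) and MAD scale
  (statsmodels RLM); t = β/SE with df = n − rank(X) (effective-df
  corrections for prewhitening/robustness are out of scope and the p-values
  are validated by simulation instead: subject-level type-I ≈ 1–5% at
  nominal q = 0.05).
- **FDR**: Benjamini-Hochberg step-up across the recording's good long
  channels, per chromophore; reject at q < 0.05.
- **Decision**: activation is present iff at least one HbO channel in
  {frontal, SMA, tongue motor} is significant **and** has β > 0; an
  optional stricter rule additionally requires β_HbR < 0. Parietal
  significances are reported but never drive the decision. Patients tested
  in up to three sessions are positive if any session is positive.

A formalized proxy for the bedside visual rating is provided
(`formal_bedside_rule`): a channel "lights up" when its HbO trace correlates
with the 5 s-lagged task indicator (r > 0.3) and its peak task-window mean
exceeds 2× the rest-period SD; the rule is true iff a lit channel lies in
{tongue motor, SMA}. This is a stated proxy for a human procedure, not a
reimplementation of it.

## Preprocessing grid search

The optimizer sweeps high-pass {0, 0.005, 0.01} Hz × low-pass
{0.1, 0.2, 0.3, 0.4, 0.5, 1} Hz × detrending {on, off} × short-channel
strategy {nearest, all, pca} on a control cohort, running the identical GLM,
and maximizes the number of participants with ≥ 1 significant channel in
{frontal, SMA} (parietal and tongue-motor significances never count). The
two cutoff lists are interpreted with drift-removal semantics — the small
values as high-pass cutoffs — because a 0.005 Hz *low-pass* would destroy
the task band and contradict the separately stated 0.2 Hz low-pass; a
`swap_cutoff_labels` flag restores the literal alternative (where the
low-pass list contains 0 = none). Ties break by total significant ROI
channels, then lexicographically smallest (highpass, lowpass, detrend,
strategy). Filter-independent stages (QC, OD, TDDR, MBLL) are computed once
per recording and reused across the 108 configurations; the sweep fits HbO
only, since the objective never reads HbR. Patient recordings never enter
the search: `apply_best_config` refuses ids seen during optimization.

Two properties of this pipeline are worth knowing when designing optimizer
benchmarks. First, it is intrinsically drift-robust — TDDR's trend-centred
derivative plus AR prewhitening neutralize even very large polynomial drift,
so filter choices only separate configurations when responses are marginal
(low contrast-to-noise); a saturated objective ties and the lexicographic
rule then favours no high-pass. Second, BH-FDR couples channels within a
recording: a subject with strong true activations in one region lowers the
step-up threshold for its own null channels, so occasional marginal false
positives elsewhere in that subject are expected behaviour, not a defect of
the ROI-exclusion rule.

## Agreement statistics

For a 2×2 table of test (bedside visual) vs reference (computational post
hoc) calls: sensitivity, specificity and concordance with 95% Wilson
intervals; Cohen's κ = (p_o − p_e)/(1 − p_e) with a normal-approximation CI
(SE = √(p_o(1−p_o)/n)/(1−p_e)) and a large-sample H₀: κ=0 p-value (Fleiss
SE). Degenerate margins flag κ as undefined rather than raising. Odds
ratios use the cross product with a Woolf (log-normal) 95% CI; any zero
cell triggers the Haldane-Anscombe +0.5 correction, and a zero cross
diagonal flags the OR undefined. On the study's printed counts
(tp=8, fp=2, fn=8, tn=18) these give sensitivity 50%, specificity 90%,
concordance 72%, κ = 0.416 with p = 0.008.

## Problem sizes

The validation suite uses full-length recordings (≈ 795 s at 10.17 Hz, 24
channels × 2 wavelengths) with 100 replicates per operating-characteristic
estimate and the full 108-configuration grid on a 10-subject cohort;
`scripts/acceptance.py` uses 40-replicate cohorts for the same quantities.
The optimizer benchmark cohort uses a low contrast (0.06 µM) with strong
cubic drift so the objective does not saturate — an optimizer cannot be
exercised on a cohort where every configuration already detects everyone.

## Known limitations

- The residual ~13% amplitude shrinkage after TDDR-matched regressors is
  not corrected; absolute µM amplitudes are mildly conservative.
- Degrees of freedom ignore prewhitening and robust-weighting losses;
  p-value calibration rests on simulation evidence, not theory.
- The bedside rule is a formal proxy; its thresholds (r > 0.3, 2× rest SD,
  5 s lag) were set a priori and are configurable, not fitted.
- SNIRF support covers the subset of the format this package writes
  (intensity data, montage, stims, metadata tags); it does not aim to read
  arbitrary third-party SNIRF files.
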