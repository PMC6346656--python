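# Methods

This note documents the models, estimators and design choices behind
`neurocog`, in the spirit of the methods documentation of statsmodels or
msprime: what is computed, under which assumptions, and where the genuinely
open choices were resolved.

## Study design emulated

A single-visit cohort of mild-dementia subjects (CDR 0.5 or 1). Each subject
contributes:

- two 30-s, 256-Hz, 19-channel (10–20 montage) EEG recordings — eyes-closed
  rest (REC) and a visual-verbal memory-encoding task (ENC) — with vertical
  and horizontal EOG and a wrist ECG recorded in parallel;
- a table of 13 regional MRI measures (five lobar volumes, five lobar mean
  thicknesses, entorhinal, hippocampal and amygdalar volumes) plus total
  intracranial volume (ICV);
- demographics (age, sex, education years), MMSE (0–30, integer) and CDR.

The analysis relates 25 ICV-normalized / standardized markers (13 MRI + 12
EEG) to log-transformed MMSE and classifies MMSE ≥ 24 versus < 24.

## EEG preprocessing

*Filtering.* The recording is polyphase-downsampled to 128 Hz and bandpass
filtered 1–30 Hz with an odd-length (type 1, exactly linear-phase) Kaiser
FIR designed for ≥ 60 dB stopband attenuation at a 0.5-Hz transition
(≈ 950 taps at 128 Hz). The filter is applied forward-backward
(`filtfilt`), so the effective attenuation doubles and the net phase is
zero — epoch timing is not skewed. Recordings shorter than the filter
transient (3 × filter length) are rejected. The EOG channels receive the
identical treatment; the ECG is only resampled so its QRS morphology
survives for beat detection. A 50-Hz notch is unnecessary: mains lies above
the 30-Hz edge.

*Ocular artifacts.* A complete ICA decomposition (FastICA, as many
components as channels) is computed on the scalp data and each component's
time course is correlated with both EOG references; components with
|r| > 0.7 (configurable) are zeroed before reconstruction. This
correlation-gated selection reproduces the intent of reference-constrained
ICA in a simple, testable form: on synthetic data it removes ≥ 80 % of the
frontal blink amplitude while changing posterior alpha power by well under
5 %. A flat or absent EOG downgrades the step to a logged no-op.

*Cardiac artifacts.* R-peaks are detected on the ECG by the classic
Pan–Tompkins chain — 5–15 Hz bandpass, differentiation, squaring, 150-ms
moving-window integration, adaptive thresholding with a 250-ms refractory
period — with peak positions refined to the local filtered-ECG maximum.
Around each beat a per-channel mean template (±150 ms) is estimated and
subtracted, removing the phase-locked cardiac field while leaving
non-phase-locked EEG untouched in expectation.

*Epoching and rejection.* 2-s epochs with 1-s overlap (a 30-s recording
yields 29 epochs; trailing partial data is dropped). Epochs whose absolute
amplitude exceeds 100 µV or whose sample-to-sample gradient exceeds 50 µV
are flagged. The exact published rejection thresholds are not fixed by the
protocol, so these defaults are explicit configuration. Flagged epochs are
masked, never deleted: every downstream average excludes them, and the mask
is part of the audit trail. The chain order — filter, EOG, ECG, epoch,
reject — is recorded in each object's history.

## EEG markers

The spectral backend is a Hann-tapered periodogram per 2-s epoch
(256 samples at 128 Hz → 0.5-Hz resolution), one-sided density scaling so
that integrated power equals signal variance.

- **IAF** — spectral centroid over 8–13 Hz, computed per epoch and channel,
  then averaged over P3, Pz, P4, O1, O2 (REC). Averaging centroids (rather
  than taking the centroid of the averaged spectrum) matches the
  "mean frequency position" reading; the two differ only when alpha power
  varies strongly across epochs.
- **Band powers** — power integrated over each IAF-anchored band, divided by
  the power in the union of the six bands ([IAF−7, IAF+16]), per epoch and
  channel, then averaged over F3, F4, C3, C4, O1, O2 (ENC). The six
  fractions sum to 1 by construction. The normalization denominator is
  configurable (`fixed_1_30` uses 1–30 Hz instead); the six-band union is
  the default because it makes the six values a proper composition. The
  REC-derived IAF anchors the ENC bands, since the dominant rhythm is only
  measurable at rest.
- **aMI** — for each epoch/channel the series is discretized into 16
  marginally equiprobable bins (rank-based, hence invariant under monotone
  amplitude rescaling) and the plug-in mutual information
  I(x_t; x_{t+τ}) is averaged over lags τ = 1…32 samples. A constant signal
  has a degenerate marginal and is defined as 0.
- **Coherence** — magnitude-squared coherence with Hann-tapered
  cross-spectra averaged over unmasked epochs, then averaged over 1–30 Hz
  and the pair set (homologous pairs → interhemispheric; F–C, F–O, C–O pairs
  per hemisphere → intrahemispheric). At least 8 epochs are required:
  single-segment MSC is identically 1. For L independent segments the
  estimator has the known positive bias ≈ 1/L at zero true coherence.
- **cMI** — the same 16-bin plug-in estimator at zero lag between pair
  channels; exactly symmetric and non-negative.

The estimator constants (16 equiprobable bins, lags 1–32, nats, 1–30 Hz
coherence averaging, Hann taper) are documented defaults in
`MarkerConfig` — the exact constants used in the original processing are
not published, so these are this package's fixed, reproducible choices.

## MRI features

Tables are ingested from CSV (or assembled from FreeSurfer `aseg.stats` /
`aparc.stats` text tables with a Desikan–Killiany lobe aggregation). Every
measure is divided by ICV. Normalizing *thickness* by a volume is
dimensionally odd but follows the blanket "all measures" rule;
`normalize_thickness=False` exempts it. Normalization is guarded against
double application.

## Outcome model and statistics

MMSE is natural-log transformed (any log base differs by a constant that
z-scoring absorbs) and z-scored; markers and covariates are z-scored.
"Generalized" regression is realized as Gaussian identity-link OLS — the
appropriate reading when residual diagnostics motivate a log transform.

*Screening.* Each marker enters its own model with age, sex (female = 1)
and education; the marker term is tested by F = t². For a single regressor
without covariates this reduces to the classical F = r²(n−2)/(1−r²).

*All-subset selection.* Every subset of candidate markers up to `max_size`
(API default 8) is fitted with covariates always included and ranked by
AICc = n ln(RSS/n) + 2k′ + 2k′(k′+1)/(n−k′−1), k′ counting all coefficients
including the intercept. Enumeration solves each subset's normal equations
from a single precomputed Gram matrix, batched per subset size (~10⁶
fits/min on one core); a tiny ridge (10⁻¹⁰ × mean diagonal) keeps degenerate
subsets finite without affecting ranking. Ties are broken toward smaller
subsets, then lexicographic marker order. The winning subsets are refitted
through statsmodels for standard errors and p-values, and a test
cross-checks the enumerator's AICc against that independent route.
Enumerations beyond 10⁷ fits are refused with advice to screen first.

*Group tests.* MMSE ≥ 24 vs < 24 groups are compared by Kruskal–Wallis
(continuous) and Yates-continuity-corrected Pearson χ² (2×2 tables) — the
continuity correction is required to reproduce the reference value
χ²(1) = 4.19 for the CDR-by-group table.

*Partial-regression data.* Added-variable pairs via Frisch–Waugh–Lovell, so
the scatter slope equals the joint-model coefficient exactly.

## Classification

RBF-SVM under leave-one-out cross-validation. For each held-out subject the
features are standardized on the training fold only and (C, γ) are tuned by
stratified inner 5-fold CV over a log-2 grid spanning C ∈ 2⁻³…2⁹,
γ ∈ 2⁻¹¹…2³ (default exponent step 2, i.e. 7×8 points; step 1 available).
Ties prefer the first grid point, making tuning deterministic under the
seed that fixes inner-fold assignment. No class weighting by default.
Covariates are excluded from the classifier features by default (the marker
subset, not the confounders, is what is being evaluated); both are
configurable. The positive class is MMSE ≥ 24. Metrics are computed from
the aggregated confusion matrix in exact rational arithmetic before
rounding to percent. A regression test guards the protocol against silent
leakage: moving standardization and tuning outside the folds changes
predictions on a crafted cohort with a scale-dominating outlier.

## Synthetic cohort

The generator is the package's test bed; its defaults are the study
conditions (111 subjects, IAF 9.71 ± 0.44 Hz, the mild-AD band-power
profile, interhemispheric/intrahemispheric coupling 0.57/0.41, MRI means and
SDs typical of early AD, MMSE 23.4 ± 3.1, a 73/38 CDR split, and a planted
six-marker outcome model — left temporal volume, frontal/parietal/occipital
thickness, theta and alpha2 power — with population R² 0.382).

*EEG signal model.* Per subject and phase: (i) an alpha sinusoid at the
subject's true IAF, posterior-weighted, 20 µV at rest and suppressed (0 µV)
during the eyes-open task; (ii) noise spectrally shaped to the subject's
band profile over the six IAF-anchored bands (100 µV² total), synthesized
with deterministic spectral amplitudes and random phases so the realized
band powers equal the configured ones; (iii) a weak 1/f background and 1-µV
white sensor noise; (iv) structured shared sources: one global source gives
all coupled channels the intrahemispheric MSC level and one extra source per
homologous pair lifts those pairs to their own target, so both coupling
targets are met exactly when intra ≤ inter, and coupling 1 on an isolated
pair makes the two signals identical (coherence 1). Because the generator
couples channels only inside the six-band union while the coherence marker
averages 1–30 Hz, measured global coherence is a fixed fraction
(≈ bandwidth ratio) of the in-band target — the recovery tests therefore
check monotonicity (Spearman ρ > 0.95 across a strength sweep), which is
the scientifically meaningful property.

*Artifacts.* Blinks: a stereotyped 300-ms biphasic waveform at a Poisson
rate (default 10/min), mirrored at full amplitude into the vertical EOG and
frontally weighted on the scalp (Fp > F > 0 posteriorly). Heartbeats: a
QRS-like complex at 70 bpm, strong on the ECG auxiliary and leaking 4 µV
uniformly into the scalp. `artifact_rate = 0` disables both (the clean ECG
auxiliary remains).

*MRI.* Multivariate normal with block correlation (0.5 within lobar
volumes, thicknesses and limbic volumes; 0.25 across), non-positive rows
resampled; ICV ~ N(1500, 130²) cm³, forced above every volume.

*Outcomes.* Latent score = Σ β·z(marker) + covariate terms + Gaussian
noise; when a population R² is configured the noise SD is set so the
systematic part explains exactly that fraction of latent variance. The
score maps affinely to the MMSE scale, is rounded half-up and clipped to
[0, 30] — integer quantization is therefore an irreducible noise floor even
at zero residual noise. CDR 1 is assigned to the lowest latent scores after
adding extra noise (1.2 × latent SD), reproducing the configured 73/38
split while keeping the MMSE–CDR association weak, as observed clinically.

*What the generator does not emulate:* cortical geometry and volume
conduction (couplings are planted directly, not propagated through a head
model), non-stationary arousal drifts, electrode artifacts other than
blinks/QRS, and any nonlinear marker–outcome relation. Passing tests
demonstrate estimator correctness and protocol integrity under the planted
model, not clinical validity on real recordings.

## Problem sizes and numerical choices

- Subset-recovery simulations run 100 replicates of n = 111 with
  enumeration capped at subset size 6 (the planted size); at the default
  candidate correlations a larger cap re-admits correlated substitutes and
  chance AICc improvements, and the exact-recovery property is a
  size-matched question. The R² calibration uses 40 replicates.
- The "low noise" recovery condition is zero residual noise — MMSE integer
  quantization remains, so recovery is high but not trivially 1.
- Coherence tests use 29 epochs (one 30-s recording) and verify the 1/L
  small-sample bias on independent noise.
- The acceptance script and the test suite use the reduced (step-2) SVM
  grid and 2 permutation replicates for the null check; both are
  configuration, not protocol, changes.
- Degenerate inputs are contracts, not crashes: named errors for invalid
  phases, non-PSD covariances, missing planted markers, all-rejected
  recordings, zero alpha power, < 8 epochs for coherence, rank-deficient
  designs, single-class folds and empty groups.

## Known limitations

- The ICA step is stochastic in initialization; it is seeded, but component
  recovery on real (non-synthetic) mixtures can vary across seeds.
- Template subtraction assumes a stable cardiac field; it underperforms on
  strongly varying beat morphology.
- The plug-in MI estimators carry the usual upward finite-sample bias
  (≈ (B−1)²/2N nats for B bins and N samples); markers are comparable
  across subjects because epoch length and bin count are fixed, but absolute
  values should not be compared across different estimator constants.
- AICc-based exhaustive search is selection-biased upward in reported R²;
  the acceptance simulations quantify this against the planted truth.
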