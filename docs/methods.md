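# Methods

## Scope and data model

All modalities share one session clock in seconds; streams are uniformly
sampled and alignment is plain timestamp arithmetic (no network
synchronization layer). Pre-stimulus windows are half-open `[t−W, t)`: the
sample at arrow onset is excluded, so stimulus-evoked activity cannot leak
into a "pre-stimulus" feature. One `TrialRecord` row is produced per
unreliable arrow regardless of how many features could be computed;
per-feature validity flags replace silent drops, and model fitting excludes
incomplete rows listwise (mixed models tolerate the resulting imbalance).

## Event schedule

Each 10-minute period carries exactly 50 arrows, 10 of them unreliable with
outcomes 6 no-lane-change / 2 incorrect / 2 correct at randomized positions.
Inter-event intervals are drawn uniformly on 13 ± 2 s and then rescaled so
the 50th arrow lands 3 s before the period ends: the arrow *count* is
authoritative and the nominal spacing yields to it (50 × 13 s does not fit
in 600 s; the realized mean spacing is ≈ 11.9 s). A period too short to hold
its arrow count at ≥ 1 s spacing is a fatal configuration error.

## ECG: R-peak detection and HRV

Detection runs once on the full record (per-trial decomposition would
suffer edge artifacts); the 10-s pre-stimulus window is then applied to the
detected peak *times*. The record is decomposed with a stationary
(maximal-overlap, non-decimated) wavelet transform, `sym4`, with
orthonormal scaling; the reconstruction keeps the detail levels whose
pass-bands `[fs/2^(j+1), fs/2^j]` overlap 5–25 Hz, where QRS energy lives —
the depth therefore adapts to the sampling rate, and the detector is
rate-agnostic (default 250 Hz). The squared reconstruction is thresholded
at 0.2 × its rolling 2-s maximum — a 2-s window always contains a beat at
physiological rates, so the rolling maximum tracks QRS amplitude and makes
the detector invariant to overall scale. (A rolling *percentile* was
considered and rejected: QRS complexes occupy only a few percent of
samples, so even a 95th percentile tracks the noise floor, which measurably
costs precision at low SNR.) Candidate peaks are separated by a 250-ms
refractory period, refined to the raw-amplitude maximum within ±50 ms, and
deduplicated within one refractory period. meanRR is the arithmetic mean of
successive peak differences; RMSSD the root mean squared successive
difference of those intervals; both require ≥ 3 peaks in the window, else
the trial's cardiac features are flagged missing.

## EEG: pre-stimulus alpha power

The continuous record is filtered before epoching with two windowed-sinc
(Hamming) FIR filters — high-pass 1 Hz with 2 Hz transition band, low-pass
40 Hz with 10 Hz transition band, lengths from the 3.3/transition rule,
forced odd — applied by centered convolution, i.e. zero-phase, so
pre-stimulus timing does not shift. Mastoid-average re-referencing is
provided for multichannel input. Epochs are the 1 s before each unreliable
arrow. An epoch is rejected if any sample exceeds ±100 µV; a channel whose
record-level amplitude lies beyond ±2 SD of the across-channel distribution
is flagged (flagging only; interpolation is out of scope, and ocular ICA is
not emulated — the generator produces no blinks by default). Each valid
epoch is linearly detrended and transformed with a single Hamming-windowed
Welch segment (segment length = epoch length, so overlap is moot),
`nfft` = next power of two ≥ the epoch (512 at 500 Hz — the unique
power-of-two length that puts a bin at 5000/512 = 9.7656 Hz, the bin
nearest 10 Hz). Power is floored at 1e−12 before 10·log₁₀ so degenerate
epochs return a finite floor instead of −∞; alpha power is the dB value at
that bin.

## Gaze dispersion

From the 3-s pre-stimulus window, samples with tracker confidence < 0.8 are
discarded; sd_x and sd_y are sample standard deviations (n−1 denominator —
the convention of the statistical environments this analysis family uses;
configurable) of the retained raw positions, and lnX/lnY their natural
logs. Fewer than 10 retained samples, or zero dispersion, flags the feature
missing (no log of zero). No saccade/fixation parsing is attempted —
dispersion is computed on raw retained samples.

## Behavior: RT and sensitivity A

The response window for an arrow is `(onset, next onset]` (arrows arrive
every ~13 s, far beyond any credible RT; the last arrow gets 10 s). The
first `U` press in an unreliable arrow's window is its hit and RT; RTs
above 2,600 ms are set equal to 2,600 ms (winsorized, not discarded —
capping is idempotent and order-preserving below the cap). `U` presses in a
reliable arrow's window are false alarms against that arrow; the first
N/I/C press after a hit is scored against the true lane-change outcome.

Sensitivity uses the Zhang–Mueller *A*: with H ≥ F,

- A = 3/4 + (H−F)/4 − F(1−H)            if F ≤ ½ ≤ H
- A = 3/4 + (H−F)/4 − F/(4H)            if F ≤ H < ½
- A = 3/4 + (H−F)/4 − (1−H)/(4(1−F))    if ½ < F ≤ H

and A(H, F) = 1 − A(F, H) below chance. It needs no z-transformation and is
defined at rates of 0 and 1 (the reason it replaces d′ here). The package
carries an independent constructive oracle: the minimum- and maximum-area
proper ROC curves through (F, H) are found by linear programming over
non-decreasing concave curves pinned at the observed point — the
minimum-area curve is additionally pinned at the origin, while the maximum
may rise vertically from it — and A is the average of the two areas. Two
numerical details matter for agreement at 1e−6: the LP grid contains the
analytic kink locations of the extremal polylines, and concavity rows are
written as slope differences so the solver's feasibility tolerance is
meaningful even for near-coincident grid points.

## Mixed-effects RT models

Fixed effects are expanded to all interactions of the named terms up to
order 3; continuous physiological predictors are z-scored over the fitted
rows *before* expansion (interaction coefficients are otherwise
scale-dependent; likelihood-ratio statistics are invariant to this affine
choice, which the tests verify), and the time period enters as a centered
numeric 1–5 covariate (a single slope per interaction, not a 4-df factor).
Random structure is crossed intercepts for participant and for trial index,
fitted as two variance components; the printed model family uses intercepts
only (a random-slope option exists but is off by default). Estimation is ML
whenever a fit feeds a fixed-effect LRT — REML likelihoods are not
comparable across fixed-effect structures — with REML available for
variance reporting.

Fitting goes through statsmodels MixedLM. Its profiled likelihood has flat
ridges on which a single optimizer can report convergence short of the
optimum, which corrupts likelihood *differences*; every fit therefore
multi-starts (L-BFGS and Powell, extending to CG/Nelder–Mead if neither
converges) and keeps the best likelihood. This was validated against lme4
on replicate null datasets: best-of-methods log-likelihoods agree to
< 1e-4 and LRT χ² statistics to < 1e-5, where single-optimizer fits were
off by up to ~14 χ² units. One test keeps lme4 (via Rscript) as a
permanent cross-check oracle.

LRTs compare nested ML fits on identical rows: χ² = 2·Δloglik clipped at 0,
df = difference in fixed-effect parameter count (the random structure is
held fixed across the pair, so variance-component boundary issues do not
arise), p from the upper χ² tail. Self-comparison returns χ² = 0, df = 0,
p = 1. AIC = −2·loglik + 2k and BIC = −2·loglik + k·ln n with
k = fixed effects + 2 variance components + 1 residual. Nakagawa R²:
σ²_fixed is the variance of the fixed-effect predictor over the fitted
rows; marginal = σ²_fixed / (σ²_fixed + σ²_participant + σ²_trial +
σ²_resid), conditional adds the intercept variances to the numerator.

`model_search` runs, in order: the four single-measure × period interactive
models with their additive nulls (1-df LRTs); the five-term order-3 model;
an 11-df LRT of all lnX-containing terms (five-term vs four-term order-3
expansions) deciding whether lnX is dropped (forceable either way); the
selected reduced model against its additive null (10 df: 14 vs 4 fixed
terms); and three sub-interaction LRTs, each comparing the reduced order-3
model against "additive plus the single tested two-way" (9 df: 14 vs 5) —
the nesting consistent with the reference analysis's printed degrees of
freedom. The tested pairs are alpha×HRV, alpha×period and HRV×period.

## Synthetic data: what it emulates, and what it does not

The generator draws, per unreliable trial, independent standard-normal
latents for alpha, meanRR, RMSSD and lnX. These drive both the waveforms
and RT:

- **RT**: intercept 900 ms; defaults β_alpha = +40, β_RMSSD = −30,
  β_period = +60 (slowing across the session), β_alpha×RMSSD = −40, all in
  ms per SD of latent (period in ms per period step, centered); participant
  intercept SD 100 ms, trial-index intercept SD 30 ms, residual SD 150 ms;
  floor 150 ms; 2% misses, 1% false alarms to reliable arrows, 95% correct
  second presses. The generator's feature→RT map is exactly the model
  family the fitting stage estimates, so recovery is well-posed.
- **ECG** (250 Hz): RR intervals i.i.d. Gaussian about the trial's mean
  (800 ms baseline, ±4% per SD of latent) with σ = RMSSD/√2 — i.i.d.
  deviations make the expected RMSSD analytically exact (35 ms baseline,
  ×e^0.3 per SD); waveforms are a biphasic ~80-ms Mexican-hat QRS of 1 mV,
  a Gaussian T-wave at 30% amplitude 300 ms later, and white noise
  (default SD 0.05 mV). No autocorrelation, respiration, or ectopy.
- **EEG** (500 Hz, "Pz"): 1/f background (exponent 1, total SD 10 µV) plus
  a 10-Hz sinusoid whose amplitude inside each 1-s pre-stimulus window is
  the trial's latent (geometric mean 8 µV — an alpha peak ~13 dB above the
  background bin, as prominent posterior alpha during passive monitoring —
  spread e^0.5 per SD), with 100-ms raised-cosine ramps outside the window.
  No blinks, no alpha outside the windows, no topography (multichannel
  synthesis exists only to exercise the ±2 SD channel rule).
- **Gaze** (120 fps): i.i.d. Gaussian scatter about screen center, σx 50 px
  (×e^0.3 per SD of latent inside the 3-s windows), σy 40 px; 10% of
  samples get confidence < 0.8.

Passing recovery tests on this generator shows the *pipeline* is correct —
windows land where they should, features track their latents monotonically,
planted coefficients come back unbiased, the interaction LRT holds its
size. It does not show that real EEG/ECG/gaze (with blinks, movement
artifacts, autocorrelated heart rate, saccade structure) would yield the
same effect sizes, and the reference study's human-data coefficients are
not reproducible from synthetic data by construction.

Model-level simulations (coefficient recovery, type-I calibration) use the
generator's latent trial-table path — features and RTs drawn directly from
the documented linear model — because refitting hundreds of mixed models
does not become more informative by adding waveform synthesis in between;
the waveform→feature path is validated separately.

## Validation problem sizes and observed behavior

- Detector: 5-min records, ~375 beats, SNR (R amplitude over noise SD) ∈
  {∞, 20, 10} with T-waves: sensitivity and PPV 100% at matching tolerance
  ±50 ms; noiseless peak times recovered within ±4 ms.
- Interaction recovery: 50 replicate studies of 25 participants × 50
  trials; planted standardized alpha×HRV coefficient 0.5 (defined in units
  of the residual SD, i.e. 75 ms; the recovered/planted ratio is invariant
  to that convention) recovered with ~1% relative error in the mean.
- Type-I error: 200 replicate null studies (no alpha–RT or HRV–RT
  coupling); the 1-df interaction LRT rejects at ≈5–7% at the 5% level
  (the long-run rate over 1,000 replicates is ≈0.056, the expected mild
  liberality of ML fixed-effect LRTs).
- Feature recovery: RMSSD within 5% at 1,000 intervals; gaze SD within 3%
  at 10,000 samples; measured alpha dB vs latent amplitude Spearman ≈ 0.95
  over 100 trials at the default alpha SNR.

## Known limitations

- Latents are mutually independent; real alpha/HRV/gaze co-vary.
- The ±2 SD channel rule is flag-only; no interpolation.
- Degrees of freedom for LRTs are asymptotic χ²; no small-sample
  (Kenward–Roger-type) correction is offered.
- The lnX drop decision is a single 11-df LRT at α = 0.05, not a general
  model-selection procedure.
- The speed–accuracy correlation report is a convenience summary across
  participants and carries no validation weight.
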