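# Methods

This note documents the generative model, the analysis conventions, the
numerical choices, and the limits of what the synthetic-data tests can
show.

## Task model

The IDED plan is generated as a walk over matching rules. Shift subtypes
(colour-to-colour, shape-to-shape, colour-to-shape, shape-to-colour; 25
each by default) are ordered by a feasibility-checked random shuffle: the
dimension sequence is a walk on {colour, shape} in which within-dimension
shifts are self-loops and cross-dimension shifts must alternate, so a
greedy sampler restricted to moves that leave a completable remainder
produces a uniform-support pseudorandom order. Run lengths after each
shift are drawn from a shuffled, approximately balanced multiset over
2–7. Each block starts with a few filler trials (trials before a block's
first shift are excluded from analysis), and only the second trial after
a shift is the "repeat" control.

Stimulus construction where the design leaves freedom: the matching
stimulus shares only the relevant feature with the target (its irrelevant
feature differs), and the distractor shares neither feature. This
guarantees a unique, unambiguous match and forces dimension-selective
attention; a config switch (`distractor_overlap`) re-enables irrelevant-
dimension overlap for users who want response conflict. Left/right
placement of the match is uniform per trial.

## Generative EEG model

Each participant's continuous recording is

1. **1/f background**: independent per channel, synthesized in the
   frequency domain with one-sided PSD `S(f) = A·f^(−α)` (α = 1 by
   default, flattened below 0.5 Hz), scaled so the 1–100 Hz band SD is
   10 µV. Because the PSD is imposed exactly, the expected wavelet power
   of the background ("noise floor") is computable by integrating
   `S(f)·|Ŵ(f)|²` over the wavelet's spectrum. A 0.5 µV line component at
   50 Hz is added for realism.
2. **Midfrontal theta bursts**: one per trial, a Hann-windowed sinusoid at
   6 Hz (±0.3 Hz jitter per trial, random phase) spanning 100–650 ms
   post-stimulus, with Gaussian spatial weights
   `exp(−d²/2σ²)` (σ = 0.6 rad) around FCz on the unit sphere.
3. **Occipital evoked burst**: same morphology, 0–200 ms, centred on Oz
   (σ = 0.5 rad), mimicking the visual evoked theta response.
4. **Behaviour**: log-normal RTs with group and condition offsets; errors
   are wrong-side presses with probability 1.0 / 2.0 / 2.7 % (repeat / ID
   / ED, both groups, pooling to 1.90 %); draws beyond the 4 s deadline
   become no-response errors.

### Calibration: profiles target pipeline-level quantities

The profile's `theta_db` values are targets for what the *analysis
pipeline measures* (mean dB over 4–8 Hz × 250–500 ms × six frontocentral
electrodes), not raw amplitudes. The calibration inverts the forward
model deterministically:

* the noise floor per analysis frequency comes from the constructed PSD
  and the wavelet spectrum, times 1.5 — the linked-mastoid re-reference
  adds half a channel's variance of independent background noise — and
  burst topography enters through `w_ch − w̄_mastoid`, because the
  reference subtracts its own share of the burst;
* the burst's wavelet power over the analysis box (and its leakage into
  the −400…−200 ms baseline window) is computed once from a noise-free
  template transformed by the same wavelet code, averaged over the
  frequency-jitter distribution by Gauss–Hermite quadrature;
* the per-condition amplitude gain then solves
  `mean_box 10·log10((P_n + g²·w²·u_act) / (P_n + leak)) = target` by
  scalar root-finding, where `leak` is the trial-mix-weighted baseline
  leakage of all conditions (the baseline is common to all trials); the
  leak is resolved by a three-step fixed point, which converges because
  the leakage term is small.

Per-trial burst power is multiplied by a log-normal variable `q` with
`E[q] = 1` (amplitude log-SD 0.5), which gives single-trial theta a
realistic right-skewed distribution.

### Theta–RT coupling

Coupling is imposed through a Gaussian copula on (burst amplitude,
log-RT): latent correlation `r` maps to Spearman's ρ via
`ρ = (6/π)·asin(r/2)`. The pipeline, however, observes theta through
noise, and two attenuation mechanisms sit between the latent copula and
the recovered Fisher z:

1. measurement noise in the single-trial box estimate, including the
   burst-noise interference term `2·Re(S·N*)` of wavelet power, whose
   per-trial samples are drawn from a seeded pilot transform of
   background-only epochs (re-referenced like real data);
2. Shepherd's Pi itself: the bootstrapped-Mahalanobis step preferentially
   removes the heavy right tail of single-trial power — precisely the
   trials carrying rank information — which attenuates the recovered
   correlation further.

The calibration therefore inflates `r` in two stages: a normal-scores
correction for measurement noise, then a forward Monte-Carlo of the
actual estimator (Shepherd's Pi on cells of the expected trial counts)
whose mean Fisher z is matched to the profile target by a linear
rescaling. Both corrections are deterministic (fixed internal seeds) and
part of the generative model, not a fit to any pipeline output.

### RT calibration

Group/condition log-RT offsets are fixed design constants (condition:
0 / +0.115 / +0.235; group: +0.33 for older; log-SDs 0.22–0.31). The
single free constant — the base log-RT — is solved analytically so that
the cohort mean of per-participant medians of the pooled
repeat/ID/ED log-normal mixture (trial weights 2:1:1) equals 718 ms.
The mixture median uses the analytic mixture CDF and a root-find.

## Analysis conventions

* **Filtering**: second-order Butterworth band-pass applied forward and
  backward (zero phase). Artifact windows: step > 50 µV marks ±400 ms;
  peak-to-peak > 600 µV in 200 ms marks ±1000 ms (400 µV on the second
  pass, which subsumes the first when no ocular hook is installed);
  peak-to-peak < 0.5 µV in 100 ms marks ±200 ms. Intervals slide sample
  by sample (the alternative, hopping windows, is not used). ICA ocular
  correction is an optional no-op hook; the generator produces no blinks.
* **Spherical-spline interpolation** uses the Perrin construction with
  spline order m = 2, 10 Legendre terms, and ridge λ = 1e−5.
* **Epochs**: −1250…3000 ms, correct repeat/ID/ED trials only; the
  −250…0 ms mean is subtracted per channel as a DC step (it cannot affect
  power ratios in the theta band); the sample at tmax is included when it
  falls exactly on the grid.
* **Wavelets**: unit-energy complex Morlet, 7 cycles, support truncated
  at 3 SD of the Gaussian envelope; output on a 50 ms grid; cells whose
  support crosses an epoch edge are NaN and flagged invalid, never
  zero-filled. The dB ratio cancels any global wavelet normalization.
  When all requested frequencies sit far below Nyquist the input is
  decimated internally (anti-aliased, grid-preserving); the passband
  difference is < 0.5 % in power and identical for signal and baseline.
* **dB normalization**: baseline = mean raw power over −400…−200 ms
  averaged across *all* of a participant's included trials, per channel ×
  frequency. Condition summaries average raw power across the condition's
  trials first and then take dB — the event-related spectral perturbation
  convention; taking dB per trial first would subtract the
  `E[log χ²]`-type offset (≈ −2.5 dB at SNR 0) and no printed group value
  would be recoverable that way. Per-trial dB remains available in
  `db_normalize` for users who want it.
* **Single-trial theta** is measured on the linear power scale with the
  participant's common-average baseline subtracted (a per-trial-baseline
  variant is behind a flag). RTs enter the correlation on the natural-log
  scale (flag for raw).
* **Shepherd's Pi**: 200 bootstrap resamples, squared-Mahalanobis removal
  threshold 6 (the published default of the method; the source does not
  state these for this analysis, so they are exposed in the API), seeded
  per participant × condition from the run's master seed. Group-level
  inference uses one-sample t-tests with BH-FDR, not the doubled-p rule.
* **Mixed ANOVA**: univariate split-plot decomposition via orthonormal
  within-subject contrasts; supports one between factor (unequal group
  sizes) and one or two within factors, each within term with its own
  error stratum. Greenhouse–Geisser ε and Mauchly's W are computed from
  the group-partialed covariance of the contrast scores (pingouin, used
  as a cross-check, does not partial out the group; the difference is
  small and only affects ε/W, never SS or F). GG adjustment is applied
  when Mauchly's p < .05; both adjusted and unadjusted p-values are
  reported.
* **Composite performance z**: the weighting that equalizes unequal
  groups is `w = N_total / (2·N_group)` per participant, applied to both
  the mean and the SD of each measure across all participants and
  conditions (the exact weighting formula is not printed in the source
  analysis; this is the symmetric reading). Natural logs throughout;
  downstream statistics are base-invariant.
* **Cohen's d**: SD-of-differences for paired contrasts (pooled-SD
  switchable), pooled SD for independent contrasts.
* **Bayes factors**: JZS with Cauchy prior scale √2/2, delegated to
  pingouin and cross-checked against dense-grid quadrature of the
  noncentral-t marginal likelihood.

## Problem sizes and what the tests show

The test suite and the acceptance script use the study-sized task (50 ID
+ 50 ED shifts per participant, ~565 trials, ≈ 27 min of recording) but
restrict simulations to the 16 channels the analyses touch and 1–20 Hz;
channel count and spectral range beyond this are irrelevant to every
extracted quantity. The acceptance script simulates the full 20 + 19
cohort; the in-suite recovery checks use 6 + 5 subjects with
correspondingly wider, precommitted Monte-Carlo intervals. Type-I-error
calibration of the ANOVA machinery runs on dependent-variable-level null
simulations (hundreds of replicates), not on full EEG cohorts.

Recovered cohort quantities are stochastic. Their per-subject spreads —
≈ 0.2 dB for a condition-mean theta value (shared-baseline noise plus
log-normal amplitude sampling), ≈ 0.145 for a single cell's Fisher z —
set the confidence intervals declared in the tests.

What passing does **not** show: the generator uses spatially independent
background noise (real EEG is volume-conducted and spatially coherent),
no ocular or muscle artifacts by default, a single fixed burst morphology,
and no between-subject variability in the theta targets (the printed
between-subject SDs of the source data are not emulated, only the means).
Parameter recovery here validates the pipeline's correctness, not its
robustness to everything real recordings contain.

## Known limitations

* The artifact detector's thresholds are the printed cohort means; the
  original procedure chose them per subject. Per-subject overrides exist
  in `ArtifactCriteria` but nothing estimates them.
* The linear mixed-effects slope analysis (theta × performance with
  Satterthwaite degrees of freedom) is out of scope; the tables the
  pipeline produces are sufficient input for standard mixed-model tools.
* `simulate_cohort` writes BrainVision triplets through a purpose-built
  writer validated by round-trips through MNE's reader; TFR containers
  are kept in memory (tidy CSV summaries are the persistent interface).
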