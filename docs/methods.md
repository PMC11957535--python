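# Methods

This note documents the models, default parameters, and numerical choices
behind `ibsense`, and what the synthetic-data generators do and do not
emulate.

## Paradigm model

Both tasks are closed loops around a physiological signal:

- **Cardiac (iBEATs).** Synchronous trials lock stimulus movement onsets to
  detected R-peaks. Asynchronous trials move at a constant period equal to
  the mean inter-beat interval (IBI) of the *preceding synchronous trial*
  scaled by exactly 0.9 ("faster") or 1.1 ("slower"). The scaling is applied
  to the period, so "faster" means a shorter period.
- **Respiratory (iBREATH).** Synchronous trials couple stimulus size to the
  belt signal; cycle landmarks are detrended zero-up-crossings. Asynchronous
  trials render a sinusoid with the previous synchronous trial's mean
  amplitude and its mean breathing frequency scaled by 1.1 ("faster") or 0.9
  ("slower") — the scaling applies to frequency here, phase 0 at trial onset.

Trial control: the first trial is always synchronous. A trial lasts at least
5 s and at most 20 s (cardiac) or 30 s (respiratory); past the minimum it
ends as soon as the infant has looked away for 2 continuous seconds (the
realized end time is `max(lookaway_start + 2 s, 5 s)`). The session ends at
80 trials, after 4 consecutive look-away-terminated trials, or on an
external fussiness signal (modeled as an optional trial index, since the
operational trigger is experimenter judgment). An attention getter of 1 s is
charged to the session clock before each trial. "Looked away" means gaze off
the screen (invalid or outside the screen rectangle), not merely outside the
stimulus AOI.

Design choices left open by the protocol: the faster/slower direction per
asynchronous trial alternates in fixed-order mode and is a seeded fair coin
in randomized mode; the default fixed condition order is strictly
alternating except every 7th trial repeats its predecessor (so occasional
sync–sync / async–async pairs occur), shipped as a replaceable documented
constant.

### R-peak detection

A software emulation of a hardware fast-response output: an event fires at
the first sample at or above the threshold after a sample below it, with a
200 ms refractory period (infant heart rate stays below 300 bpm). Only event
times are modeled; no ECG waveform morphology (P/QRS/T) is rendered.

### Respiratory cycle extraction

The analysis window is mean-detrended; peaks and troughs are located with a
minimum 0.3 s separation and refined by local parabolic interpolation.
Frequency is the reciprocal of the mean peak-to-peak interval, amplitude the
mean half peak-to-trough excursion. For a pure sinusoid sampled at 100 Hz
both are recovered to better than 1e-6 (frequency exactly, amplitude to the
parabolic-interpolation error ~1e-7 of the amplitude).

## Synthetic looking-time model

`simulate_looking_time_table` draws, per infant *i*,

    delta_i ~ Normal(delta, between_sd)                 (true preference, ms)
    LT_sync  ~ TruncNormal(base + delta_i/2, within_sd; 0, trial_max)
    LT_async ~ TruncNormal(base - delta_i/2, within_sd; 0, trial_max)

Truncation is by the truncated distribution (resampling), not clipping, so
no point mass accumulates at 0 — zero looking times are an explicit
downstream exclusion decision, not a generator artifact. Defaults: `base` =
6258.66 ms, the midpoint of the 9-month cardiac condition means (7020.62 and
5496.70 ms); `trial_max` = 20 000 ms. One global seed spawns an independent
substream per infant, so growing `n_infants` never reshuffles earlier
infants, and power curves over nested sample sizes share common random
numbers.

What the generator **emulates**: between-infant preference heterogeneity,
within-infant trial noise, truncation by trial length, artifact and
technical-error plumbing, alternating condition order starting synchronous.
What it does **not** emulate: trial-order and fatigue effects, stimulus- or
side-specific preferences, within-session autocorrelation of attention,
age-dependent noise profiles, or eye-tracker drop-out structure. Passing
tests therefore demonstrate correctness and calibration of the *analysis
chain*, not realism of any specific infant population.

With this generator, the per-infant mean difference has SD
`sqrt(between_sd² + 2 within_sd²/m)` for `m` trials per condition, which
gives a closed-form paired-t power oracle used by the test suite.

## Preprocessing

The exclusion chain runs in a fixed order: technical errors → physiological
artifacts (optionally asynchronous trials only) → zero looking times →
±k SD outliers → per-infant minimum trial count. SD rejection is computed at
trial level across all infants within a condition and is deliberately
**single-pass** — the group SD is not recomputed after removals, so the
chain with the SD step active is not idempotent. SD rejection precedes the
minimum-trial criterion so inclusion reflects analyzable trials. Artifact
flags are graded: for the cardiac task `none` = all R-peaks detected,
`small` = ≥ 85% detected, `large` = < 85%; for the respiratory task by the
fraction of the trial overlapped by a movement transient (`small` < 0.2).
Each rejection rule keeps a flag subset (e.g. `strict` keeps only `none`,
`pct85` keeps ≥ 85% detection); under the default grading some rule labels
coincide behaviorally but remain distinct multiverse dimensions because
their defining criteria differ. The optional log transform is
`ln(LT_ms + 1)` applied before condition comparison.

The discrimination score `|m_sync − m_async| / (m_sync + m_async)` lies in
[0, 1], is invariant to swapping condition labels, and is undefined (infant
dropped, reason logged) when a condition is missing.

## Inference

- **Cohen's d.** Standardizer = root-mean-square of the two condition SDs,
  `sqrt((s1² + s2²)/2)`. This is the convention validated by the worked
  examples; a plain average of SDs differs at the second decimal.
- **TOST.** Standardized bounds ±d·SD(diffs) (the d_z convention; the bound
  convention in the original analyses is not fully recoverable, so this
  choice is documented rather than asserted against published TOST
  statistics). Verdicts: `equivalent` if the larger one-sided p < α;
  `non-equivalent` if the (1−2α) CI lies outside the bounds; else
  `inconclusive`.
- **JZS Bayes factor.** Cauchy prior on the standardized effect, default
  scale √2/2. The marginal likelihood uses the substitution δ = r·tan(u),
  mapping the Cauchy measure to a uniform on (−π/2, π/2), then adaptive
  quadrature; agreement with a dense-grid trapezoid oracle is better than
  1e-4 relative. The posterior of δ is evaluated on a 4001-point grid
  spanning at least ±8 prior scales and ±10 approximate SEs, sampled by
  inverse CDF (20 000 draws), and rescaled to the ms scale.
- **ROPE.** Percentage of the 95% highest-density interval's mass inside the
  region of practical equivalence, computed sample-wise (fraction of
  HDI-members inside the ROPE). The HDI is the shortest interval containing
  95% of samples.
- **Beta mixed model.** Mean-precision Beta likelihood, logit link, constant
  φ, Normal random intercept per participant. Marginal ML by *adaptive*
  Gauss–Hermite quadrature, default 15 nodes: per group the integrand's mode
  is found by damped vectorized Newton steps (analytic first and second
  derivatives of the beta log-density with respect to the linear predictor)
  and nodes are centred/scaled at the mode. Optimization is L-BFGS-B on
  (β, log φ, log σ) with box bounds log φ ∈ [−5, 12], log σ ∈ [−8, 3] so
  degenerate data (constant outcomes push φ → ∞) walk to a cap instead of
  derailing the line search. Standard errors come from the numerically
  differentiated observed information; BIC = −2ℓ + k·ln(n_obs). With σ fixed
  at 0 the model collapses to plain beta regression and matches an
  independent ML fit to ~1e-6. Looking times are mapped into (0, 1) by
  dividing by the maximum trial duration and applying the
  Smithson–Verkuilen squeeze `(y(n−1)+0.5)/n`.
- **Marginal contrasts.** Condition effect averaged over age-group levels on
  the logit scale (weight 1 on the main effect, 1/m on each of the m−1
  interactions under treatment coding), exponentiated to an odds ratio with
  a delta-method CI and a t reference with n_obs − k degrees of freedom.
- **Multiple testing.** None beyond the primary analyses; post hoc
  comparisons are reported unadjusted, matching standard practice for these
  designs.

## Specification curve

The decision grid is declarative and user-replaceable; defaults enumerate
2·4·4·2·2·4·2 = 1024 cardiac and 2·4·6·2·2·4·2 = 1536 respiratory paths in
deterministic lexicographic order. Every path yields exactly one result —
failures and paths retaining fewer than 3 infants are recorded with
direction `none`, never raised — so curve totals are conserved. The
"linear mixed model" test option is a Gaussian random-intercept model on
(optionally log) looking time with a condition fixed effect and Wald p.

Joint inference: each specification contributes a signed z
(`sign(effect) · Φ⁻¹(1 − p/2)`); the curve statistic is Stouffer's
`Σz/√K`. Null curves are built by flipping all condition labels of a random
half of infants (within-infant exchangeability under the null; every
infant's trial count is preserved), and
`p = (1 + #{null z ≥ observed z}) / (B + 1)`.

## Problem sizes and calibration checks

The test suite verifies, among others: type-I error of the full
simulate–summarize–test chain at α ± 3 Monte-Carlo SEs over 2000 null
replicates; uniformity of the Stouffer permutation p under the null
(Kolmogorov–Smirnov at α = 0.01, 200 replicates of B = 200 permutations on a
single-specification grid with 12 infants); unbiasedness of the recovered
condition difference (2000 replicates); and beta-mixed-model fixed-effect
bias and 95% Wald-interval coverage over 200 replicates of 200 groups × 10
observations. Paradigm invariants are property-checked over 500 seeded
sessions mixing gaze policies and order modes.

## Known limitations

- The beta mixed model supports a single random intercept (no random slopes
  or crossed factors) and a constant precision φ.
- The Gaussian mixed-model option inside the multiverse uses REML with a
  Wald p and no Kenward–Roger-style small-sample correction.
- The session engine abstracts gaze to look/look-away bouts; rendering to
  500 Hz samples is a separate generator, and eye-tracker calibration is
  assumed perfect.
- Respiratory "synchrony" is modeled at the level of cycle landmarks and
  mean cycle parameters, not continuous amplitude tracking of the rendered
  stimulus.
- Fixed-order sequences are a documented reconstruction; any real study's
  exact sequence can be substituted as a constant.
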