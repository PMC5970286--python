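# Methods notes

This note records the models, conventions and design choices behind
`stepurge`, in the spirit of a statistical methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Wear-time model

Heart-rate *presence* is the wear signal: the device samples HR every few
seconds while worn, so any minute without a sample is treated as off-wrist.
Conventions, each of which is a genuine choice rather than a fact of the
world:

- **Target window** `[10:00, 22:00)`, half-open, exactly 720 minutes.
  Participants were not asked to wear the device overnight, so wear
  accounting outside this window would only add noise.
- **Nonwear window**: a *maximal* run of ≥ 90 consecutive missing-HR minutes
  inside the target window. Maximality matters: counting overlapping 90-min
  placements would turn any 180-minute gap into an automatic exclusion,
  defeating the one-window tolerance below.
- **Clipping**: gaps are intersected with the target window *before* the
  90-minute test. A device left off from 08:30 to 11:30 contributes only its
  10:00–11:30 portion (90 min — exactly qualifying). Whether a gap spanning
  22:00 should count toward the next morning is unknowable from the rules as
  stated; clipping resolves it symmetrically and is flagged as a convention.
- **Valid day**: fewer than two nonwear windows AND ≥ 360 wear minutes in the
  target window (the 359/360 boundary is exercised in tests). Daily steps
  are summed over the full calendar day, not just the target window.
- **Eligibility**: ≥ 42 valid days in any arrangement. "Six weeks" is not
  required to be consecutive — studies of this design tolerate gaps and
  extend participation to fill them.
- Sparse exports: a minute absent from the CSV is missing HR and zero steps
  (device off), not a data error.

## Panels

- **Acute lookbacks** are half-open `[t − w, t)` with `t` truncated to the
  report's minute: the minute containing the report is excluded so steps
  taken *while* reporting cannot contaminate the exposure.
- **Coverage retention**: an urge report enters the acute model for window
  `w` only if ≥ 80% of its lookback minutes were worn (configurable). The
  panel itself keeps all valid-day events with their coverage fractions; the
  fit applies the filter, so one panel serves every window length.
- The day panel requires ≥ 1 urge report that day — mean daily urge is
  undefined otherwise. Multiple reports in one minute are all retained.
- **Midpoint split**: with `n` valid days the midpoint is the
  `floor(n/2)+1`-th valid day; "pre" is the first `floor(n/2)` valid days and
  "post" is the midpoint day onward (a 4-day record splits 2/2).
- **Outlier rule**: Tukey fences at 1.5 IQR beyond the quartiles, with
  quartiles from numpy's linear-interpolation quantile convention (the rule's
  source does not fix a convention; this one is declared and tested, and the
  resulting mask is affine-invariant).

## Pooled FGLS

The estimator is the classical two-step feasible GLS for panel-level
heteroskedasticity: pooled OLS → per-participant residual variance σ̂ᵢ² →
WLS with weights 1/σ̂ᵢ². Choices:

- Participants with < 3 observations take the pooled residual variance
  instead of their own (avoids degenerate weights); so does any group with a
  zero variance estimate.
- No autocorrelation structure: the panels are unbalanced and unequally
  spaced, so there is no common lag grid; a within-day/lag correction is out
  of scope by design.
- Inference is normal-reference (z); 95% CIs are β ± 1.96·SE. Per-person
  fits (below) use the t reference instead, as is standard at n ≈ 10–80.
- When all groups share one variance the weights are equal and FGLS collapses
  to pooled OLS exactly; under strong variance heterogeneity the reweighting
  is more efficient. Both are asserted in tests.
- Adjusted day-level model covariates: age (years, continuous), sex, race
  and IPAQ-high (binary), baseline cigarettes/day (continuous). The coding
  is declared here because conventions differ; it is configurable.
- A subtlety worth knowing: with *slope* heterogeneity (extreme responders),
  stage-1 residuals of the responders absorb their deviation from the pooled
  slope, inflating their σ̂ᵢ² and *down-weighting* them in stage 2. The
  pooled FGLS acute slope on a responder-driven cohort is therefore smaller
  in magnitude than the participant-share-weighted average of true slopes.
  This is a property of the method, not a bug, and it grows with panel
  length (better-estimated variances → sharper down-weighting).

## Responder analysis

- Per-participant OLS at two levels (day: mean urge vs daily steps; window:
  urge vs 30-minute steps), both per 1000 steps, each requiring ≥ 10 usable
  rows and nonzero step variance; otherwise the participant classifies null.
- **Extreme responder**: 95% CI excludes zero with the same sign at BOTH
  levels. Requiring two-level consistency is the main false-positive guard;
  no multiplicity correction is applied across participants (~50
  simultaneous tests), so the classification is exploratory by construction.
  Under a fully null generator the empirical inverse-responder rate is
  bounded in the acceptance suite at ≤ 2.5%.
- The pooled "mean individualized slope" is the unweighted mean of responder
  betas with a CI from the SE of that mean (inverse-variance weighting would
  be a defensible alternative; unweighted matches the simple presentation
  this analysis style uses). A singleton summary reuses the fit's own SE.
- Stratified urge means around the 500-step cutoff use mean ± 1.96·SE over
  episodes, ignoring within-person clustering — a deliberate simplification
  (the CIs are anti-conservative); the stratified episode table is exported
  for boxplot-style display.

## Synthetic cohort generator

What it emulates, and why it is shaped the way it is:

- **Steps** are a two-part process: smooth "ambient" Poisson ambling (30% of
  volume) spread over a 24-hour diurnal profile, plus discrete walking bouts
  (8–25 min at ~95 steps/min, Poisson-counted per day). Bouts are essential,
  not decoration: with a smooth Poisson process the 30-minute lookback sums
  would have an SD of ~15 steps and no acute effect would be identifiable;
  with bouts the SD is several hundred steps, matching the fact that a
  500-step half-hour cutoff meaningfully splits real episodes. Day-level
  (lognormal, σ=0.25) and participant-level (lognormal, σ=0.3) activity
  multipliers provide the between-day and between-person spread.
  Mean daily steps defaults to 6000 — a realistic level for adult smokers;
  the source design does not publish a value.
- **Nonwear**: per-day Poisson gaps (rate 1.5/day, uniform 30–200 min,
  starting 09:00–21:00) — deliberately straddling the 90-minute rule so some
  gaps must and some must not trigger the detector. These defaults put the
  valid-day fraction near the ~81% retention the design reports; the
  injected intervals are recorded in the ground-truth sidecar so validity
  can be recomputed independently of the detector.
- **Urge reports**: 3–4 prompted reports/day at fixed preferred clock times
  (10:30/13:30/16:30/19:30, jittered ±20 min; 3 vs 4 chosen to average 3.4)
  plus a small spontaneous Poisson stream (0.05/day) during waking hours,
  totaling ~290 reports per participant over 84 days. The prompted *share*
  under these defaults (~98%) is higher than the ~80% a real cohort shows;
  the flag feeds no model, so the report volume was prioritized.
- **Latent urge** is additive-linear — participant intercept + day slope ×
  (daily steps, globally centered) + window slope × (30-minute steps,
  centered at the waking-rate equivalent) + Gaussian noise — then rounded
  and clamped to 1–9. Centering constants are population-level, so they
  shift intercepts only and never bias slope recovery. Noise defaults
  (SD 1.2, participant lognormal spread σ=0.3 on the SD) keep the clamp
  essentially inactive for non-responders (< 1% of mass at the rails), so
  round-and-clamp attenuation is negligible relative to Monte-Carlo error in
  recovery tests, while per-participant noise spread gives FGLS real
  heteroskedasticity to work with.
- **Effects**: population day and 30-minute slopes default to zero, with an
  11% extreme-responder subpopulation at −0.15 urge/1000 daily steps and
  −1.66 urge/1000 30-minute steps. This is the internally consistent
  configuration for a responder-driven acute effect: 6/53 × 1.66 ≈ 0.19 per
  1000 ≈ 0.019 per 100, and removing the responders nulls the pooled effect.
- **Participant intercept spread defaults to 0.** This is a deliberate
  model-consistency choice, not an oversight: pooled FGLS carries no
  cluster-correlation correction, so nonzero random intercepts combined with
  between-person activity differences would make its nominal 95% CIs
  undercover by construction (Moulton-type inflation). With the default
  generator the calibration properties asserted in the acceptance suite are
  properties of the estimator, not artifacts of an error structure the
  estimator never claims to handle. The `intercept_sd` knob exists for
  studying exactly that misspecification.
- Timestamps are timezone-naive local time with no DST transitions.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: smoking events and the flooring effect of
a recent cigarette (no time-since-last-cigarette process), HR magnitude
(only presence matters downstream), autocorrelated urge dynamics,
participant-preference heterogeneity in prompt schedules, device sync
artifacts, and cluster-correlated urge intercepts under the defaults (see
above).

## Power simulation

The day-level design power tool draws bivariate (steps, urge) day pairs with
observation-level correlation r and a fraction `icc` of each variable's
variance at the participant level, then applies the Fisher-z correlation
test with the design's intraindividual correlation accounted for through an
effective sample size: n_eff = N / (1 + (m−1)·icc²) for m days per
participant (the design effect for the product of two equally clustered
variables). At icc = 0 this is the plain pooled test and agrees with the
closed-form Fisher-z power, which the acceptance suite checks at the
n = 50 × 20, r = .12 design point. An unadjusted pooled test would be
oversized for icc > 0 (empirically ~14% at icc = 0.3 under the null), which
is why the adjustment is part of the simulated analysis and not optional.

## Problem sizes in the test suite

Simulation-based checks run at sizes chosen to make their Monte-Carlo error
small relative to the asserted tolerances while keeping the suite a
few-minutes affair: slope recovery at 20 participants × 30 days × 200
replicates (with eligibility scaled to ≥ 15 valid days), CI coverage at
12 × 25 × 200, the null responder-rate bound at 8 × 25 × 500, and responder
recovery at the full 53 × 84 study scale × 100 replicates. The acceptance
script analyzes one 53 × 84 cohort and a 4000-replicate power run.

## Known limitations

- FGLS inference ignores within-person correlation of repeated residuals;
  with cluster-correlated errors its CIs undercover (documented above).
- Responder classification has no multiplicity control across participants.
- Stratified-episode CIs ignore clustering.
- The generator's urge process is serially independent given steps; real
  craving dynamics are autocorrelated.
- The IQR outlier rule and midpoint split depend on declared conventions
  (quantile interpolation; even-n split) that other implementations may set
  differently.
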