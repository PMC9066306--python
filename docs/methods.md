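# Methods notes

## Generative observer model

An observer is parameterized per modality by internal noise σ_int (degrees),
effective sampling n_samp (≥ 1) and a lapse rate.  On each 2AFC trial the
observer pools `round(n_samp)` elements drawn without replacement from the
100-element stimulus, perturbs each by independent Gaussian noise of SD
σ_int, takes the circular mean (axial, i.e. double-angle, for orientations)
and answers with its sign; with probability `lapse` it instead guesses.
This is exactly the two-parameter observation model the analysis estimates
— no late/decision noise, and no noise-exclusion failure, is added — so in
the small-noise regime accuracy has the closed form
Φ(offset / √((σ_int² + σ_ext²)/n_samp)), which the tests use as an oracle.

Fractional n_samp is meaningful on the estimation side (the MTN transform
returns continuous values, including values below 1) but a generative
sampler needs an integer count, hence the rounding; this deliberate
mismatch is why recovery tests use integer ground-truth n_samp.

External noise is *nominal*: elements are drawn on the real line with the
stated SD and then wrapped onto the circle (360°) or axial domain (180°).
The staircase, the MTN and the transform all refer to the nominal pre-wrap
SD.  At large SDs wrapping flattens the accuracy-vs-noise function, which
is physically correct and is what makes high-MTN estimates noisier.

## Psychometric function and QUEST

The Weibull is the Watson–Pelli log-intensity form with guess rate 0.5,
slope β = 3.5 and lapse 0.01.  A per-parameter-set offset ε is solved
analytically so that p(threshold) = 0.84 exactly: thresholds are defined by
the 84%-correct criterion, so the estimate is anchored to that criterion
regardless of Weibull internals.

QUEST keeps a discretized posterior over log10 threshold on a grid of
start ± 6 with step 0.02 (covering three prior SDs of 2; resolution far
below any effect of interest), places each trial at the posterior mean
(QuestMean) and reports the posterior mean as the threshold.  Conditions in
which a larger physical value is harder (the external-noise SD staircase)
run on a negated log axis internally, inverted on output, because QUEST
assumes performance non-decreasing in intensity.  Proposals are clamped to
presentable stimuli (offset ≤ 90°, coherence ≤ 1) and the posterior is
updated at the clamped value actually shown.  Staircase starting points are
2.5° mean offset, 0.001° SD and 50% coherence.

Degenerate numerics: if an update empties the posterior it is re-normalized
in log space before a degeneracy error is raised; with a non-zero assumed
lapse the likelihood is bounded away from 0, so this path is defensive.

## Session structure and screening

Averaging sessions interleave the no-noise and high-noise 75-trial
staircases with 15 catch trials uniformly at random (165 trials); coherence
sessions are 75 + 15 (90 trials).  Sides are independent 50/50 per trial;
catch trials reuse the criterion stimulus (SD 0 at the fixed offset, or
100% coherence); block boundaries are annotations only.  Signal-element
counts use round-half-up of coherence × n.

Screening mirrors the study rules: failure to produce four consecutive
correct responses within 20 easy trials, four or more errors on the 15
catch trials (the smallest count not significantly above chance at α = 0.05
by the one-sided binomial test), incomplete sessions, or a coherence
threshold at or above 100%.  Motion-task failures drop the participant
entirely; orientation-task failures drop only the orientation analyses.

## Synthetic cohorts

`CohortSpec` defaults draw 48 children per group aged 8–15, log-normal
parameter spreads (median σ_int 6° motion / 4° orientation, median n_samp
2.5, log-SDs 0.40/0.45), lapse uniform on [0, 0.04] (matching the low
catch-error proportions such tasks produce), a mild improvement of both
parameters with age (−0.04 and +0.03 log-units/year around age 11.5), and a
1.3× motion internal-noise multiplier in the dyslexic group — the direction
and rough size of the reported group difference.  These defaults land
thresholds in the plausible operating range of children on these tasks;
everything is configurable via YAML.

What passing tests on synthetic cohorts show: the pipeline plumbing,
estimator calibration and statistics behave correctly for observers that
follow the observation equation.  What they do not show: anything about
real children whose behaviour departs from that model (noise-exclusion
failure, crowding, serial dependence, response-time structure are not
modelled).

## The MTN → sampling transform and its re-calibration

`fit_participant` uses the published quadratic-exponential coefficient sets
(motion 0.0001/0.0357/−1.8093; orientation 0.0006/0.0652/−1.6843), applied
to MTN in linear degrees — the polynomial form only makes dimensional sense
in linear units, and the zero-MTN intercepts then align with the
observation equation's closed-form limit.

`calibrate_transform` re-derives the coefficients independently: it
simulates the MTN of the full circular generative observer for integer
n_samp 1–20 at the task's fixed offset (bisection on the accuracy-vs-SD
curve) and regresses log n_samp on [MTN², MTN, 1].  Two design choices are
pinned by algebra rather than fitting: (i) the representative internal
noise of the calibration observer is taken from the published intercept via
n(MTN=0) = z(0.84)²·σ_int²/offset² (≈ 18.3° motion, ≈ 9.75° orientation);
(ii) closed-form anchor points from the observation equation are added
below the smallest simulated MTN, where wrapping is negligible and the
equation is exact, because the sub-unit-sampling branch cannot be generated
by drawing a whole number of elements.  The freshly calibrated transforms
agree with the published ones to within ~10% (orientation) and ~25%
(motion, worst at the high-MTN end where wrapping curvature is strongest)
across MTN 10–60°.

## Statistics

* Mann–Whitney: exact permutation null when n1·n2 ≤ 400 and tie-free,
  otherwise tie-corrected normal approximation; rank-biserial
  2·U1/(n1·n2) − 1, positive when the first (reference) group tends larger;
  the reported W defaults to U of the first sample and is configurable
  because rank-sum conventions differ between packages.
* JZS Bayes factor: noncentral-t likelihood marginalized over a
  Cauchy(0, scale) prior on the standardized effect (scale default 1.0,
  exposed because 0.707 is the other common default), by Gauss–Legendre
  quadrature after a tangent substitution; an independent inverse-gamma
  g-marginalisation route is kept as a cross-check.
* Bayesian rank test: latent-normal data augmentation on the pooled rank
  order, chromatic (odd/even) Gibbs updates of the latents, conjugate
  updates of the shift δ and its mixture variance, Savage–Dickey BF₁₀ with
  a Rao-Blackwellised posterior density at δ = 0; defaults 5 chains ×
  10⁴ sweeps with the Monte-Carlo SE reported from per-chain spread.  Ties
  are broken by stable sort order.  On normal data it tracks the parametric
  JZS factor of the underlying observations; it is an approximation in its
  own right, not a replica of any particular GUI package's sampler.
* Quade rank ANCOVA: rank DV and covariate (mid-ranks), centre to deviation
  scores, regress, and t-test the residual deviation ranks between groups;
  a constant covariate degrades to a plain rank t-test with a warning.
  Null simulations (n = 48 + 48) put the type-I error at ≈ 0.05.
* Power analysis: smallest integer per-group n whose noncentral-t power
  meets the request; reproduces the 48-per-group design figure at d = 0.747,
  α = 0.05, 95% power, two-tailed.
* No multiple-comparison correction is applied across the six hypothesis
  rows, matching the pre-registered analysis plan.

## Numerical and design choices

* Catch-trial criterion semantics: the cutoff is the smallest error count e
  whose one-sided binomial p-value P(X ≥ n−e | chance) reaches α.  As α → 1
  this tends to n (only total failure has p = 1); for α = 0.05, n = 15 it
  is 4.
* Angles are serialized in linear degrees and coherences as proportions;
  log10 staircase units never appear in files.
* Reported tables round to 2 decimals; stored CSVs keep full precision
  (shortest round-trip float repr).
* Seeds: every stochastic stage takes an explicit seed; cohort generation
  spawns per-participant and per-task child streams from a SeedSequence, so
  runs are reproducible from the manifest alone.

## Problem sizes

Simulation-backed checks run at sizes chosen to keep the whole suite quick
while leaving clear statistical margins: 200 staircases for the QUEST bias
check, 8 000–40 000 trials per cell for accuracy oracles, 20 observers with
full sessions for end-to-end recovery, 6 000 trials per bisection probe for
transform calibration, and 2 000 simulated null datasets for the ANCOVA
calibration.

## Known limitations

* The recovery precision of n_samp from a single 75-trial staircase is
  information-limited: the MTN posterior SD (~0.05–0.06 log10 units) is
  near the Fisher bound for this trial budget, and the transform's slope
  amplifies it, so median relative errors of 20–35% across observers are
  expected and seed-dependent.
* The coherence-task observer reuses the averaging pooling model on
  signal+noise mixtures; observers limited by segregation/noise exclusion
  would behave differently.
* The Bayesian rank test's exact numerical agreement with any specific
  software's Bayesian Mann–Whitney is out of scope.
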