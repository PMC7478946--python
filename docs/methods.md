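# Methods

`choicetrace` models within-participant binary food choice from a
mouse-tracking task in which every pair of 18 foods is presented once
(153 trials per participant), together with the decision-conflict
signatures of the cursor paths and the motivational structure of the
food ratings.  This note documents the models, the estimation choices,
what the synthetic-data generator does and does not emulate, and the
design decisions taken where more than one reading was defensible.

## Trajectory conflict metrics

**Angle-AUC.** For a path `p_0 … p_m` and chosen-target location `a`,
each step `d_i = p_{i+1} − p_i` is compared with the direction to the
target from the step's origin, `t_i = a − p_i`, and the metric is the
mean of `acos(d_i·t_i / (|d_i||t_i|))` over steps where both vectors are
nonzero.  Index bookkeeping choices: `n` is the number of *steps* (not
points); steps of zero length, and the degenerate final step whose
origin already sits on the target, carry no direction and are excluded
from both the sum and `n`; the cosine is clamped to [−1, 1] before
`acos`.  This is the only reading under which every term of the sum is
defined.  The metric is an average *angle* in radians (0 for a perfectly
direct path, at most π) — not a geometric area; a conventional
signed-area diagnostic (`signed_area_auc`) is provided separately and is
never substituted for it.

**x-flips** count sign reversals of the horizontal increments; zero
increments are skipped carrying the previous sign, so a pause is not a
reversal.  A minimum-movement threshold is configurable and defaults to
0 (a pure sign change counts).

**Preprocessing.** Raw screen samples (pixels, y increasing downward)
are cut at the picture-onset threshold — the cursor rising 10% of the
vertical resolution above the start box — re-expressed with the first
retained sample at the origin and y increasing toward the response row,
and mirrored horizontally for left-corner choices so every path heads
for a canonical right-side target (both metrics are
reflection-invariant; the mirroring only standardizes plots and
downstream conventions).  Trials whose post-onset duration exceeds
4000 ms are flagged as timeouts and excluded from all analyses.

## Design and model inputs

All `n(n−1)/2` unordered food pairs are enumerated per participant, in
an independently shuffled order with uniform-random side assignment.
Because "chosen-minus-non-chosen" difference scores with outcome ≡ 1 are
degenerate as a regression problem, each trial carries a uniformly
random *reference* option: difference scores are reference-minus-
alternative and the outcome codes whether the reference was chosen.
This reparameterization is sign-symmetric — swapping the roles negates
the differences and flips the outcome, leaving every odds ratio
unchanged (verified by test).  For the conflict analyses, where the sign
of the advantage of the *selected* option is meaningful (choosing the
better-liked food predicts less conflict), chosen-relative difference
scores are used instead.

Trial-level predictors are z-standardized within participant (sample
SD); the person-level moderator (DEBQ-R restrained eating) and the
covariates age and BMI are z-standardized across participants.
Cross-level interactions are products of the already-standardized parts
(standardize-then-multiply), matching per-predictor standardization.

## Mixed models and estimation

Trials (Level 1) are nested in participants (Level 2).  Three families
are used: binomial-logit for choice (odds ratios), Gaussian-identity for
the angle-AUC, Poisson-log for x-flips (incidence rate ratios).  The
random structure is a participant intercept plus at most one random
slope on a Level-1 predictor, with the intercept–slope correlation
estimated freely.

Gaussian models are fitted with statsmodels `MixedLM` (ML; REML for the
final refit of a winning model).  Binomial and Poisson models use an
own maximum-likelihood estimator under a Laplace approximation: per
participant the random-effect mode is found by damped Newton iterations
and the marginal likelihood contribution is evaluated at the mode with
the usual Gaussian curvature correction; the random-effect covariance is
parameterized by its log-Cholesky factor and all parameters are
optimized jointly (L-BFGS-B, one perturbed restart on failure).
Fixed-effect standard errors are Wald, from the numerical Hessian of the
Laplace log-likelihood; p-values use the normal reference distribution
for all families (the degrees-of-freedom method behind the emulated
tables is not known).  Calibration was verified by simulation: at the
default study design the estimator is unbiased (mean recovered
calories × restraint coefficient −0.1630 vs truth −0.1625 over
replicates) and its Wald SEs match the Monte-Carlo SD of the estimates
(0.062 vs 0.060).  At zero random-effect variance the fixed effects
agree with single-level GLM fits within Monte-Carlo error (the GLM is
the independent oracle in the test suite, never the implementation).

`AIC = −2ℓ + 2k` and `BIC = −2ℓ + k·ln N` count fixed effects plus
random-(co)variance parameters (plus the residual variance for Gaussian
models).

**Top-down selection.**  Stage 1 fits the "beyond-optimal" fixed
structure (all motives, their restraint interactions, covariates) with a
random intercept.  Stage 2 compares random structures — intercept-only
and each candidate slope — on AIC with BIC as tie-breaker.  Stage 3
backward-deletes fixed terms: candidates are interactions first, then
main effects not involved in surviving interactions, tried in order of
decreasing p; a deletion is kept when it does not raise AIC by at least
2 (the conventional evidence threshold; configurable).  Covariates get a
final screen: a non-significant covariate is dropped unless its removal
changes the significance pattern of the remaining terms, and every
decision is logged in the selection trace.  Stage 4 refits the winner
(REML when Gaussian).  Note that hand-specified model structures may
contain an interaction without its main effect or a random slope without
its fixed effect — the winning conflict models have exactly that shape —
so the marginality rule binds the *selection path*, not the spec syntax.

**Goodness of fit.**  For binomial fits a Hosmer–Lemeshow grouped
chi-square is computed on deciles of the conditional fitted
probabilities (df = groups − 2); its null distribution was verified by
simulation (mean ≈ 8 for deciles on well-specified fits).

**Observed power.**  Power of a fixed effect is estimated by simulating
the outcome from a generative truth (coefficients plus random-effect
covariance) at the fixed study design, refitting the same specification,
and counting Wald p < α, with an exact Clopper–Pearson interval on the
proportion.  Refits are warm-started at the truth, which makes 200
replicates of the full winning choice model (random intercept + health
slope, 62 × 153 design) run in about three minutes on one CPU.

## The synthetic-data generator

The generator's defaults are the emulated study conditions: 62
participants, 18 foods, exhaustive pairing, and outcome models whose
coefficients are the winning-model estimates of the four analyses.

* **Participants.**  Restrained eating is drawn from a truncated normal
  on [10, 50] whose *truncated* moments are solved to match the reported
  sample moments (M = 25.0, SD = 8.11); naively truncating
  N(25, 8.11²) would inflate the mean by ≈ 0.6 because the bounds are
  asymmetric.  Age and BMI are moment-matched the same way and are pure
  nuisance covariates (zero true effect).  Task order (`cond_first`) is
  counterbalanced.
* **Foods and ratings.**  Foods carry fixed latent health and calorie
  profiles.  The profiles are strongly anti-correlated
  (`latent_corr = −0.92`), deterministically so across seeds, because
  this collinearity is a study condition, not noise: it is what
  reproduces the printed winning-model standard errors (log-scale SEs
  0.068 for calories, 0.057 for calories × restraint), and the reported
  observed power (81.1% for calories × restraint) is only attainable
  under those SEs.  The calibration rule was to match the printed SEs;
  power follows.
* **Palatability.**  The rating analyses fit two *separate* two-level
  models (health channel, calories channel) on the same palatability
  outcome.  With anti-correlated predictors, generating from either
  printed coefficient set alone would bias the other channel's refit by
  the omitted variable.  The generator therefore inverts the
  omitted-variable mapping at the empirical correlation r between
  z-health and z-calories — `γ_h = (a_h − r·a_c)/(1 − r²)` and
  symmetrically, likewise for the interactions — so each separate refit
  recovers its printed coefficients in expectation.  Ratings are clamped
  to the 0–100 scale; with the reported residual variance (σ² ≈ 1036,
  SD ≈ 32) this censors ~15% of draws and attenuates the refitted
  health coefficients somewhat, which is visible in the recovered main
  effect but keeps the interaction within its reported interval.
* **Choices.**  Bernoulli outcomes from the winning-model coefficients
  applied to the person-standardized difference scores, plus a
  participant intercept (variance 0.058) and a random health slope.  The
  printed slope quantity (0.491) is labeled ambiguously; it is treated
  as the slope *variance* with zero intercept–slope correlation, and the
  correlation reading is available via configuration
  (`choice_health_slope_kind="correlation"`).  Reaction times are a
  lognormal placeholder calibrated so that ~1.8% of trials exceed the
  4000 ms deadline, which reproduces the emulated analysis count
  (≈ 9317 of 9486 trials) after timeout exclusion.
* **Conflict.**  In `metrics` mode the angle-AUC is Gaussian around its
  linear predictor (truncated at 0) and x-flips are Poisson — exact
  model structure, used by all recovery tests.  In `paths` mode actual
  cursor paths are built (quadratic Bézier toward the chosen corner,
  sinusoidal lateral perturbation, 10 ms sampling) whose curvature and
  oscillation are monotone in the same linear predictors; path mode
  makes no exact metric promise and is validated by property tests
  (zero amplitude → straight line → both metrics 0; angle-AUC monotone
  non-decreasing in amplitude).
* **Intake.**  Per participant × food, grams consumed out of 100 g
  offered are Binomial with log-odds `logit(0.1) + ln(1.10) ×
  choice count`; baseline proportion and offered grams are configurable
  (neither is reported, 0.1 and 100 g are plausible round defaults).

**What the generator does not emulate.**  Real rating distributions are
not Gaussian-with-clamping; real trajectories have autocorrelated motor
noise, velocity profiles and pre-onset hesitation that the Bézier
placeholder lacks; RT dynamics (drift, sequential effects) are not
modeled; desire-to-eat ratings are palatability plus noise and enter no
winning model.  Passing recovery tests therefore demonstrates that the
*analysis pipeline* is correct and well-calibrated under the assumed
hierarchical structure — not that these models would fit arbitrary real
mouse-tracking data.

## Problem sizes and numerical choices

Recovery checks run at the emulated design (62 × 153; 1,116 rating
rows); observed power uses 200 replicates (Monte-Carlo SD ≈ 2.8
percentage points at 81% power); unit tests use miniature studies
(10–30 participants, 6–12 foods).  Inner Newton iterations stop at
gradient ∞-norm 10⁻⁹ with step halving; log-SD parameters are bounded in
[−8, 4] (a boundary fit is flagged singular, mirroring lme4's
`isSingular`); the acos argument clamp and the 10⁻¹² jitter on
Cholesky factors are the only other numerical guards.  Degenerate inputs
fail loudly: constant predictors within a participant raise a
degenerate-predictor error naming the group, all-zero-length paths raise
an undefined-metric error, and consumed > offered grams is a data error.

## Known limitations

The Laplace approximation has a small bias for Bernoulli outcomes with
large random effects (negligible at the variances used here, as the
seed-averaged recovery test shows).  The Gaussian path relies on
statsmodels MixedLM, which can report boundary variance estimates on
near-singular problems; such fits are flagged rather than hidden.
p-values are Wald/normal for all families; no Satterthwaite or
Kenward-Roger correction is attempted.  The angle-AUC is in principle
sensitive to the cursor sampling rate, which the emulated task does not
report; metrics-mode generation sidesteps this, and path-mode tests are
qualitative by design.
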