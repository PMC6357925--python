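# Methods

## The task environment

The Iowa Gambling Task (IGT) is simulated as four decks A–D. Every selection
of a deck pays that deck's fixed gain; losses arrive according to the deck's
loss frequency, expressed as loss events per 10 consecutive selections of
that deck (a "cycle"). The default schedule is

| deck | gain/pick | losses per cycle | loss magnitude | EV per cycle |
|------|-----------|------------------|----------------|--------------|
| A    | +100      | 5                | 250            | −250         |
| B    | +100      | 1                | 1250           | −250         |
| C    | +50       | 5                | 50             | +250         |
| D    | +50       | 1                | 250            | +250         |

Two loss-timing modes are provided. In the default `deterministic_cycle`
mode the k loss events fall on fixed, evenly spread positions of the cycle
(positions 10·i/k, i = 1..k), so the per-cycle expected values above are
exact identities, not asymptotic limits. In `bernoulli` mode each selection
loses independently with probability k/10, and the per-cycle values hold in
expectation. The classic administration of the task varies loss sizes
within a cycle for decks A and C; here each loss event has the constant
magnitude shown above, which preserves every per-cycle expected value while
keeping the schedule a four-number object. Variable-magnitude schedules can
be added behind the same `PayoffSchedule` abstraction.

A session is 120 trials: 20 practice trials followed by 100 experimental
trials. Scoring and model fitting consume only the experimental trials.
The simulator restarts the agent (zero expectancies, fresh deck cycles)
at the start of the experimental block, so the scored 100 trials are a
self-contained task instance; whether practice outcomes carry into the
scored trials is unknowable from the reporting conventions of this
literature, and starting from zero is the conservative choice.

Behaviour is scored by the net score (C+D) − (A+B) over the 100
experimental trials, the same quantity per consecutive 20-trial block
(five block net scores), and the four deck-selection counts. A KEAT-26
total strictly above 22 labels a subject high-risk; the threshold is
configurable, and the strict inequality follows the screening convention
for the Korean EAT-26.

## The PVL model

The Prospect Valence Learning model turns the trial's net outcome
x(t) = gain + loss (losses stored as non-positive numbers) into a
subjective valence with a prospect-theory power utility

u(t) = x(t)^a if x(t) ≥ 0, and −λ·|x(t)|^a if x(t) < 0,

with feedback sensitivity a ∈ [0,1] and loss aversion λ ∈ [0,5]
(λ = 1 weighs losses and gains equally; λ = 0 ignores losses). A zero
outcome has zero valence for every a (the 0^0 corner is routed to the
zero branch). Per-deck expectancies decay and update by

E_j(t) = A·E_j(t−1) + δ_j(t)·u(t),

where δ_j(t) indicates the chosen deck and A ∈ [0,1] is the
learning/retention parameter (A = 0 is memoryless; A = 1 accumulates).
Choice follows a softmax over θ·E_j with sensitivity θ = 3^c − 1,
c ∈ [0,5]; c = 0 gives uniform random choice. Some of the source
literature describes θ as trial-dependent although the printed formula has
no t in it; both the printed constant rule (default, `as_printed`) and a
genuinely trial-dependent θ(t) = (t/10)^c rule are implemented behind one
flag, and every output records which rule was used.

Net outcomes are multiplied by a payoff scale of 0.01 before the utility
(configurable). This keeps θ·E in a numerically benign range and matches
the magnitudes on which the parameter ranges above are conventionally
reported. Expectancies start at zero, so trial 1 contributes log(1/4) to
the likelihood of any deck. Per-trial probabilities are floored at 1e−12
inside the log; the softmax is computed with max-subtraction. The same
recursion (one numba kernel) is the generative agent, the MLE objective
and the MCMC likelihood — a single code path, verified in tests against a
deliberately naive trial-by-trial recomputation to 1e−10.

## Estimation

**Hierarchical Bayesian (default).** Each group is fitted independently.
Parameters are sampled on an unconstrained scale z through scaled-logistic
links onto their ranges ((0,1) for a and A, (0,5) for λ and c); subject
offsets are z_{i,p} ~ Normal(μ_p, σ_p) with weakly-informative hyperpriors
μ_p ~ Normal(0,1) and σ_p ~ Half-Normal(1). The sampler is adaptive
Metropolis-within-Gibbs, vectorised across chains and subjects:

* joint random-walk updates of each subject's 4-vector, with a proposal
  covariance learned per subject during burn-in (the subject posteriors
  are anisotropic and strongly correlated — notably a with λ, which trade
  off along a likelihood ridge because the scaled deck gains sit at 1.0
  and 0.5, leaving a informed mostly through losses);
* exact Gibbs draws for μ;
* log-scale Metropolis for σ;
* interweaved non-centered moves that shift μ and rescale σ while holding
  the standardised offsets fixed, which breaks the location–scale funnel
  that stalls purely centered samplers when subject-level information is
  weak.

All adaptation runs during burn-in only and is frozen afterwards. The
default configuration is 3 chains, 500 burn-in sweeps, 1,000 kept draws
per chain, with every seed derived deterministically from the call's seed.
R-hat and effective sample size (arviz) are reported for every parameter
at the subject and population levels; any R-hat above 1.1 (or undefined)
flags the fit with a warning — results are returned, never silently
discarded and never silently trusted. With 100 trials per subject the
weakly identified a and λ marginals can retain R-hat ≈ 1.1–1.2 at this
draw budget; the flags are the honest report of that.

Group-level summaries are reported two ways: the across-subject mean and
SD of the subjects' posterior means (the layout used when groups are
compared nonparametrically afterwards), and posterior summaries of the
population location link(μ) and scale σ.

**Maximum likelihood.** Per-subject bounded L-BFGS-B over the parameter
box, best of n random interior starts plus a fixed central start,
deterministic given the seed. A fit that cannot beat the uniform-choice
baseline n·log(1/4) is flagged `uninformative`. MLE is the fast
per-subject estimator used by the cohort-scale sign checks and agrees with
the hierarchical fit in rank order of subjects (Spearman ρ > 0.5 on
synthetic cohorts with spread learning parameters).

**A caveat on testing shrunken estimates.** Hierarchical shrinkage pulls
subject posterior means toward the group location. For parameters the data
barely identify per subject (a, and to a lesser degree λ, at 100 trials),
the shrunken estimates collapse to near-constants within each group, and a
between-group rank test on them effectively compares two noisy group-level
locations with inflated apparent sample size — it can declare spurious
group differences. The statistics battery runs on whichever estimate table
it is given; for between-group nonparametric tests on weakly identified
parameters the independent per-subject MLE table is the more conservative
input, and both tables are produced by the fitting driver.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: 42 high-risk
and 43 control subjects; per-subject PVL parameters drawn from group-
specific truncated normals on each parameter's range; covariates (KEAT-26,
SDS, STAI state/trait, age, BMI) from truncated normals within instrument
ranges, with KEAT-26 constrained to the correct side of the high-risk
threshold (so generated labels always agree with the labelling rule);
and each subject's full 120-trial session simulated by the PVL agent on
the default schedule. Ground-truth parameters are stored for recovery
testing. Parameters and covariates are drawn independently within group —
no parameter–severity coupling is imposed, because no such coupling is
quantified in the group-level summaries the generator is built from.

Truncation shifts moments, so the generator numerically moment-matches the
underlying (μ, σ) of each truncated normal to the configured mean/SD by
least squares (mean error weighted above SD error). Some configured
moments are unattainable in this family: a normal truncated at 0 has
coefficient of variation strictly below 1, while the loss-aversion targets
(e.g. mean 0.355, SD 0.390) and the high-risk consistency target exceed
that. There the match keeps the mean and concedes a slightly smaller SD
(λ achieves ≈0.35 against the 0.39 target); `moment_match` reports the
achieved moments, and the fidelity tests assert agreement with them.

What the synthetic cohorts do **not** emulate: at the configured group-
mean parameters the PVL agent shows the well-known preference for the
infrequent-loss decks (B and D prominent), and group differences in net
scores are weak — the behavioural group gap seen in human cohorts is not
guaranteed to re-emerge from parameter differences alone. Passing
pipeline tests on these cohorts therefore demonstrates that the machinery
(scoring, fitting, statistics) is correct and calibrated, not that the
generative model reproduces human effect sizes. The null-cohort generator
(both groups drawn from the control distribution, arbitrary labels) is
the type-I-error harness for exactly that calibration question.

## Statistics

* ANCOVA: outcome ~ group + covariates by least squares; type-III group F,
  partial η²; with zero covariates it reduces exactly to one-way ANOVA.
  The default covariate set is (SDS, STAI-state, STAI-trait): with 85
  subjects this yields the (1, 80) between-subject and (4, 320)
  within-subject error dfs that a three-covariate model implies. Any
  subset is selectable.
* Mixed-design (split-plot) ANCOVA: block (5 levels, within) × group
  (between) with covariates, computed via orthonormal within-subject
  contrasts; sphericity-assumed averaged F for block, block × group, with
  Greenhouse–Geisser ε reported alongside (uncorrected F primary). Group
  is effect-coded and covariates centred, so the block main effect is the
  unweighted grand-mean effect at the covariate means. Follow-ups:
  per-block ANCOVA contrasts tagged `bonferroni_5`, and per-group
  repeated-measures ANOVA across blocks (no covariates, matching the
  asymmetric convention of reporting covariate-adjusted between-group
  contrasts but plain within-group trend tests).
* Mann–Whitney U with midranks; the reported statistic is
  min(U_x, n₁n₂ − U_x); exact null distribution for untied samples with
  n₁·n₂ ≤ 400, tie-corrected normal approximation otherwise; one- and
  two-sided p both recorded. Fully tied inputs return U = n₁n₂/2, p = 1.
* Pearson r with the t-transform p; case-resampling bootstrap variant
  (default 10,000 resamples, seeded) reporting the percentile 95% CI and a
  sign-crossing bootstrap p (twice the smaller tail proportion beyond 0,
  capped at 1). Degenerate resamples are redrawn a bounded number of
  times, then dropped with a recorded count. The percentile bootstrap
  undercovers mildly at n ≈ 50 (measured ≈ 93% against the nominal 95%),
  a standard small-sample property of the percentile method.
* Two-sample t: pooled-variance by default (df n₁+n₂−2, matching the
  equal-df reporting convention for demographics), Welch behind a flag.

Bonferroni handling is bookkeeping, not mutation: unadjusted p-values are
reported with an `adjustment` tag recording the family size, never
adjusted and simultaneously compared against an adjusted α.

## Problem sizes and numerical choices

The test suite and drivers use these scales as the package's standard
desk-scale conditions: likelihood-oracle checks on 100 random parameter ×
sequence pairs (≤ 10 trials); hierarchical recovery on 20 agents × 100
trials (2 chains × 500 kept draws); MLE recovery on 50 replicates × 500
trials; calibration on 200 null cohorts and 400 bootstrap-coverage
replicates (1,000 resamples each); the end-to-end direction check on 20
seeded cohorts of 42 + 43 subjects with per-subject MLE. Optimiser
bounds are the closed parameter boxes; ties in the softmax are impossible
for finite expectancies; all stochastic entry points take explicit seeds
and derive child seeds through `numpy.random.SeedSequence`.

## Known limitations

* The hierarchical sampler is a random-walk scheme; at the default draw
  budget the weakly identified a and λ marginals mix slowly (flagged via
  R-hat). Gradient-based samplers would mix better but are outside the
  dependency footprint.
* Constant per-event losses; no within-cycle loss-size variation.
* No model comparison (WAIC/LOO) and no alternative utility or update
  families; the theta-rule flag is the only model variant.
* Covariates and parameters are independent within group by construction,
  so covariate-adjusted analyses on synthetic cohorts test calibration
  rather than confound structure.
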