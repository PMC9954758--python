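# Methods

## The analysis model

For each cognitive predictor `x` and reading outcome `Y`, the pipeline fits

    Y = b0 + b1*x + b2*OF + b3*(x*OF) + e

by ordinary least squares, where `OF` is the correlation-weighted sum of the
*other* predictors' z-scores. The substantive hypothesis is moderation:
`b3 < 0`, i.e. the slope of reading on any single factor steepens as the other
factors weaken. Standard errors use the unbiased residual variance and the
inverse cross-product matrix; degrees of freedom follow the `n - p` convention
(`n - 4`). One-tailed p-values are lower-tail Student-t probabilities of
`b3/SE(b3)` (an explicit flag flips the direction for other applications).

Two deliberate choices shape the fit:

* **No centering before the product term.** All variables are z-scores or
  weighted sums of z-scores; centering would change the (meaningless in
  isolation) main-effect coefficients but not `b3`, its SE, or any p-value.
  Interpretation at substantively meaningful levels is delegated to the
  simple-slopes output (lines at the focal predictor's mean and ±1 SD).
* **No multiple-comparison correction.** The interaction is predicted in every
  one of the outcomes × predictors tests, not in "at least one"; the report
  metadata states this.

### Two samples, two estimands

Weights and fits intentionally come from different samples. Correlation
weights use the largest table available, with **pairwise-complete**
observations per predictor/outcome pair — in clinical databases each test is
administered to a different subgroup, and discarding a child's phonological
score because their memory score is missing would waste most of the sample.
The interaction models use **listwise** deletion over the three model
variables, which in the canonical design yields the complete-case subsample
(55 of 266). Passing the same table twice is a supported single-sample mode,
flagged in the metadata.

### Composites and screening

Reading accuracy and speed composites are arithmetic means of the text, word
and nonword component z-scores, and a composite is missing whenever any
component is — this reproduces the complete-case structure instead of quietly
averaging whatever is present. Predictor screening selects candidates with
non-negative pairwise correlations against both outcomes; within a
user-declared group of alternative measures for one construct, only the
maximizer of `r_accuracy + r_speed` survives, and an exact tie is a hard error
demanding an explicit choice (there is no principled automatic tie-break).
Candidates with fewer than 3 pairwise-complete observations are unevaluable
and never selected. All measures are assumed oriented so higher z = better
performance; the reader does not re-orient columns.

## Bayes factors

The alternative hypothesis is a uniform prior on the interaction coefficient
over a user-supplied interval (in the canonical use, `[lower, 0]` — a negative
effect of bounded plausible size); the null is the point at zero. The
likelihood is normal, centred at the observed estimate with SD equal to the
standard error **after** inflation by `1 + 20/df**2`. That inflation is
precisely the published small-sample correction for replacing the Student-t
likelihood of an OLS estimate with a normal one, so the normal form plus the
correction is the coherent pairing; at df = 51 the factor is 1.008 and it
vanishes as df grows. Prior intervals are required inputs per analysis row —
they encode substantive judgements about plausible effect sizes that the
package has no basis to derive.

BF10 has the closed form `{[Φ((u−b)/s) − Φ((l−b)/s)]/(u−l)} / φ(b; 0, s)`.
Numerically, the normal mass is evaluated with survival functions whenever the
whole prior interval lies below the estimate, avoiding catastrophic
cancellation between two CDF values near 1; a property test holds the closed
form to the defining integral (adaptive quadrature) at relative 1e-8. If the
prior-averaged likelihood underflows entirely, BF10 is clamped to the smallest
positive float (decisive evidence for the null) rather than returning 0.

Evidence categories follow the conventional bands: < 1/3 evidence for the
null, [1/3, 3] inconclusive, (3, 10] moderate, (10, 30] strong; "very strong"
(> 30) is an extension beyond the conventionally quoted bands, added for
completeness. Output tables print BF10 to 3 decimals.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not any
particular clinical population:

* **Factors.** Five named cognitive factors drawn from a zero-mean multivariate
  normal with an exchangeable correlation matrix (off-diagonal 0.3 by default)
  — all such measures correlate positively in school-age cohorts; fully
  configurable.
* **Generative law.** Latent index `MFi = Σ w_i f_i` with nonnegative weights
  (defaults 0.25 IQ, 0.35 phonological awareness, 0.30 RAN, 0.20 visual
  search, 0.20 memory — phonological awareness largest, per the usual ordering
  of reading predictors; illustrative, not population estimates). Latent
  reading is `MFi + gamma*min(0, MFi - tau) + N(0, noise_sd)`: efficient above
  the threshold `tau`, difficulties proportional to the shortfall below it.
  The hinge is the minimal piecewise-linear operationalization of
  "proportional to the gap below threshold"; smooth alternatives are out of
  scope. `gamma = 0` recovers a purely additive model — the null for
  calibration studies.
* **Observed reading.** One latent reading value per child feeds all six
  observed components (text/word/nonword × accuracy/speed), each adding
  independent `N(0, component_noise_sd)`; composites then follow the
  cohort-table convention.
* **Ascertainment.** Children are retained iff at least one reading z-score is
  ≤ −2, mirroring diagnosis-based referral. Ascertainment conditions on the
  outcome and therefore distorts effect magnitudes relative to the population;
  recovery tests assert the *sign* of the interaction, never its size.
* **Missingness.** A random subset of exactly `n_complete` children keeps all
  predictors; every other child loses a random nonempty predictor subset
  (each with probability 1/2), reading columns always kept. This is MCAR; real
  missingness in clinical databases is by test-battery era, which is not
  modelled (no data on it).

Defaults: `n_total = 266`, `n_complete = 55`, `tau = 0.5`, `gamma = 1.5`,
`noise_sd = 0.6`, `component_noise_sd = 0.4`, cutoff −2. `tau` and `gamma`
were fixed by a feasibility computation on the generative law itself: the
default draw must retain at least `n_complete` children after ascertainment
for essentially every seed, and at `tau = 0.5, gamma = 1.5` the expected
retention is ≈ 0.37 (≈ 99 of 266; the probability of falling below 55 is
~2e-9). A threshold half an SD above the factor mean with strong
below-threshold amplification describes a demanding skill in a referred
population — illustrative values, to be replaced by the user's own when
studying a specific population.

**Seeding.** All randomness flows from one integer seed; each stage (factors,
reading noise, missingness) draws from a named `SeedSequence` substream, so a
stage is bit-reproducible in isolation and regenerating with the same seed
yields an identical cohort.

**What passing simulation tests does and does not show.** The generator shares
the analysis model's Gaussian, homoskedastic, MCAR world. Calibration and
sign-recovery results therefore validate the *machinery* (estimators, tails,
seeding, pipeline plumbing) under the model's own assumptions; they say
nothing about robustness to skewed z-score distributions, floor effects in
accuracy scores, era-structured missingness, or comorbidity-driven referral —
all real features of clinical reading data.

## Simulation studies (`recover`, and the calibration tests)

Per replicate: draw `n` fully observed children pre-ascertainment, generate
reading at the study's `gamma`, estimate weights on the replicate itself,
build the OF index excluding the focal predictor (memory by default), fit, and
record the one-tailed decision. Under `gamma = 0` the conditional mean of the
outcome given (x, OF) is exactly linear and homoskedastic (joint Gaussianity),
so the population interaction coefficient is zero and the test should reject
at the nominal rate; the suite checks the rate over 1000 replicates of n = 500
against the 99% binomial band around 0.05. Under `gamma = 1` the mean fitted
interaction coefficient over 200 replicates is negative with rejection rates
near 1 at n = 500. Those problem sizes keep each study under ~30 s while
leaving Monte-Carlo error far smaller than the margins asserted.

## Numerical and degenerate-input policy

* Duplicate child identifiers, unparseable cells (named by line and column),
  unknown columns, constant predictors, rank-deficient designs, fewer than 5
  complete cases, non-positive SEs, degenerate prior intervals and
  non-positive-definite correlation matrices are hard errors, never warnings.
* CSV floats are written at full precision and parsed with Python's exact
  round-trip parser, so write→read is lossless.
* Reports contain no timestamps: rendering the same analysis twice is
  byte-identical, which makes end-to-end reproducibility checkable with a file
  diff.
* Ten fits may in principle use different `n` (listwise deletion per fit); the
  report records each fit's own `n` and `df`.

## Known limitations

* Uniform H1 priors only; no half-normal/normal priors and no default-Bayes
  machinery — and no procedure for deriving prior intervals, which are inputs.
* No robust or heteroskedasticity-consistent standard errors.
* The generator has no genetic/environmental levels, no longitudinal
  structure, no comorbidity, and MCAR-only missingness.
* Published tables of this design are only partially recoverable from their
  own printed (rounded) numbers; the test suite documents one frequentist row
  and notes which Bayes-factor rows are exactly recoverable. Recomputation
  from rounded inputs is a consistency check, not an audit of the original
  unrounded analysis.
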