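# Methods

## Model and assumptions

The outcome is the number of skilled antenatal care (SANC) visits a mother
reports for her most recent birth. It is modelled as a zero-and-one
inflated Poisson (ZOIP) mixture: with probability φ₀ the count is a
structural zero, with probability φ₁ a structural one, and with the
remaining probability φ₂ = 1 − φ₀ − φ₁ it is Poisson(λᵢ) with
log λᵢ = xᵢᵀβ. The inflation masses are constant across mothers (no
covariates on φ₀, φ₁): the scientific focus is the mean of the count
component, and the masses are treated as population-level nuisance
fractions. Observations are assumed independent; the survey's two-stage
cluster design, weights and strata are deliberately ignored, matching the
unweighted regression this pipeline reproduces. Records with any missing
value are dropped (complete-case analysis), which is unbiased when
missingness is completely at random.

The regression design is fixed: an intercept, 19 treatment-coded dummies
for twelve categorical covariates (reference levels: urban, age <20, no
education for both parents, poor, first birth, non-working, media
non-exposed, no decision participation, violence non-justified, unwanted
pregnancy, no terminated pregnancy), the survey year as a quantitative
code (2011→1, 2014→2, 2017-18→3, 2022→4), and the product of the year
code with the rural indicator — p = 22 columns in total. Column order is
a documented constant so coefficient vectors are comparable across runs.
Datasets containing a single survey wave drop the year and interaction
columns (they are collinear with the intercept and the rural dummy) and
skip the trend stage with a warning.

## Likelihood, parameterisation and optimisation

The log-likelihood is the sum of three blocks: zero counts contribute
log(φ₀ + φ₂e^{−λᵢ}), one counts log(φ₁ + φ₂λᵢe^{−λᵢ}), and larger counts
the Poisson term plus log φ₂. Both mixed branches are evaluated with
log-sum-exp so neither addend underflows at large λ, and factorials use
the log-gamma function, keeping the log-pmf exact for counts into the
hundreds. Linear predictors beyond ±700 would overflow `exp`; the public
likelihood refuses them with an explicit error rather than clipping.

The optimizer works on an unconstrained parameter vector
(β, γ₀, γ₁) with (φ₀, φ₁) = multinomial-logit(γ₀, γ₁), which keeps the
masses strictly inside the simplex no matter where the line search
wanders (φ₂ is computed as exp(−log D) from the logit normaliser D, not
as 1 − φ₀ − φ₁, to avoid catastrophic cancellation for extreme γ).
BFGS minimises the *mean* negative log-likelihood with analytic
gradients, relative tolerance 10⁻⁸ and at most 500 iterations; a fit is
declared converged only when the per-observation gradient infinity-norm
falls below 10⁻⁵, and non-convergence is flagged, never silently
discarded. Initial values follow a two-stage scheme: β from a Poisson
GLM (statsmodels IRLS; fallback to a log-mean intercept if it fails), and
(φ₀, φ₁) from an intercept-only three-parameter ZOIP fit started at the
empirical excess of zeros/ones over Poisson(ȳ), clipped into the simplex
interior. A restricted mode fixes φ₀ = φ₁ = 0, reducing the model to
Poisson regression; it exists for nested-model comparisons and as an
oracle check against the GLM.

Standard errors come from the observed information: the Hessian of the
total log-likelihood at the MLE on the unconstrained scale, by central
finite differences of the analytic gradient (step 10⁻⁵·max(1, |θ|)),
inverted and mapped to the natural (β, φ₀, φ₁) scale through the logit
Jacobian. P-values are two-sided Wald normal. Mass estimates within 10⁻⁶
of zero are boundary solutions: they are flagged, their SEs are labelled
unreliable, and a singular information matrix at such a fit degrades to
missing SEs rather than an error. Effects are reported as mean ratios
exp(βⱼ).

## Score test for simultaneous inflation

Before fitting, a partial score (Lagrange-multiplier) test checks the
Poisson null against zero-and-one inflation without covariates. At the
null MLE λ̂ = ȳ the score for the two masses is
U = (Σ[1{yᵢ=0}/p₀(λ̂) − 1], Σ[1{yᵢ=1}/p₁(λ̂) − 1]) with pⱼ the Poisson pmf
at λ̂. Estimating λ costs information; the efficient (Schur-complement)
per-observation covariance works out to V₁₁ = 1/p₀ − 1 − λ,
V₂₂ = 1/p₁ − 1 − (1−λ)²/λ, V₁₂ = −λ, and the statistic Uᵀ(nV)⁻¹U is
referred to χ²₂ (three null parameters, k − 1 = 2 df). The quadratic form
is two-sided, as is standard for this reference distribution; a
boundary-corrected mixture-of-χ² reference would be slightly more
powerful but is not implemented. The χ² calibration is not assumed: a
parametric-bootstrap oracle recomputes the statistic on Poisson(λ̂)
resamples, and the test suite verifies type-I error within [0.03, 0.07]
at α = 0.05, uniform null p-values, and agreement of analytic and
bootstrap p-values within 0.03 on average.

## Nonparametric screening and descriptives

Unadjusted associations use the Kruskal-Wallis test (scipy, tie
correction always on — visit counts are heavily tied), with pairwise
two-sided Mann-Whitney U follow-ups only for covariates with more than
two levels whose Kruskal-Wallis p falls below the screening α (default
0.05, configurable). Pairwise p-values are reported unadjusted to match
the report layout this pipeline reproduces; Bonferroni adjustment is
available behind a flag. Mean visit counts carry normal-approximation
95% intervals, mean ± 1.96·SD/√n.

## Synthetic generator

The generator emulates the pooled four-wave sample: per-year sizes
6,956/4,304/4,819/4,712; covariates drawn independently within year from
the published per-year category percentages (renormalised — one published
2022 marginal sums to 108% and is flagged in the logs); outcomes drawn
from the ZOIP mixture at the published coefficient vector with masses
(0.172, 0.011). One master seed spawns per-stage child streams
(covariates, outcomes, missingness) so each stage is individually
reproducible. Optional missingness is injected completely at random at a
per-field rate to exercise the complete-case filter, and a truth sidecar
(JSON) records the generating parameters for recovery tests. What the
generator does **not** emulate: within-year dependence among covariates
(only marginals are published, so independence is a documented
simplification), household/cluster structure, sampling weights, and any
covariate dependence of the inflation masses. Passing recovery tests
therefore demonstrate correctness of the estimator under the stated
mixture, not robustness to survey design effects.

## Numerical and design choices

- Contrast intervals are formed on the log scale and exponentiated
  (bounds stay positive); a symmetric-on-ratio variant exists behind a
  flag for sensitivity. Delta-method endpoints agree with a 5,000-draw
  parametric bootstrap within 5% in the test suite.
- Trend ratios are λ-scale mean ratios; an E[Y]-scale variant
  (φ₁ + φ₂λ) would differ by a near-constant factor and is not reported.
- The missing marker in CSV input is an empty field or `NA`; the survey
  year accepts both the hyphen and en-dash spellings of 2017-18.
- "Don't know" style responses in the source empowerment indicators have
  no dedicated code in the schema; they should be exported as missing.
- Degenerate inputs: empty record lists and incomplete cases are rejected
  when building the design; a covariate observed at a single level is
  reported as a warning (its dummy is constant and absorbs into the
  intercept) rather than an error, so one-record profiles remain
  constructible; an all-zero sample makes the score test undefined and is
  an error.

## Problem sizes used in the test suite

Simulation-backed tests use fixed seeds throughout. The Wald-coverage and
SE-calibration study runs 200 replicates of n = 2,000 under the full
design; the end-to-end recovery study runs 100 replicates at the pooled
n = 20,791; score-test calibration uses 1,000 Poisson-null replicates of
n = 2,000 and 200 power replicates. These sizes were chosen so each check
has enough Monte-Carlo resolution for the asserted bands. One band is
checked at its achievable rate rather than a conventional one: at the
pooled size the sampling SD of φ̂₁ is ≈0.0028, so a ±0.005 recovery band
spans only ~1.8σ; the suite asserts unbiasedness, SE calibration, and the
rate consistent with that width instead of a 95% hit rate no unbiased
estimator could achieve there.

## Known limitations

- No survey weights or cluster-robust variances; estimates describe the
  unweighted pooled sample.
- Inflation masses are covariate-free by design; if structural zeros in
  fact vary with covariates, φ̂₀ is an average and β is interpretable only
  for the count component.
- The score test is intercept-only; a covariate-adjusted inflation test
  is out of scope.
- Direct maximisation only (no EM variant); with 22 coefficients and two
  masses BFGS converges in well under a second at n ≈ 20,000, so the
  extra machinery is unnecessary.
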