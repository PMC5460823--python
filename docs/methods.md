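# Methods

## Model

`bivpois` fits a bivariate count model built by the marginal–conditional
approach. For subject *i* with covariate vector *xᵢ* (leading 1 for the
intercept):

- Y₁ᵢ ~ Poisson(λ₁ᵢ), with ln λ₁ᵢ = xᵢ′β₁ (marginal part);
- Y₂ᵢ | Y₁ᵢ = y₁ ~ Poisson(λ₂ᵢ · y₁), with ln λ₂ᵢ = xᵢ′β₂ (conditional
  part).

The joint pmf is the product g(y₁)·g(y₂|y₁). At y₁ = 0 the conditional law
is a point mass at y₂ = 0 (we use the conventions 0⁰ = 1 and
y₂·ln y₁ = 0 when y₁ = 0, which make the exponential-family form
well-defined there). Useful identities: E Y₁ = λ₁, E Y₂ = λ₁λ₂, and the
implied correlation of the pair is √(λ₂/(λ₂+1)), which motivates the
moment estimator r = √(l/(l+1)) with l = ȳ₂/ȳ₁.

The right-truncated variant restricts Y₁ to {0..k₁} and Y₂|y₁ to {0..k₂},
renormalizing each factor by the reciprocal Poisson cdf at the bound
(c₁ and c₂(y₁)). A single global k₂ is used for every y₁ (the bounds type
leaves room for per-level bounds, but applications we target use a common
cap). Evaluating the truncated pmf outside its support raises a
`SupportError`; the structurally impossible point (y₁=0, y₂>0) inside the
support returns probability 0 — the two cases are deliberately distinct.

Truncated moments are **defined** by direct finite summation over the
support. The incomplete-gamma identity for the truncated mean,
E[Y|Y≤k] = λ·Q(k,λ)/Q(k+1,λ) with Q the regularized upper incomplete gamma
function, is implemented only as an independent cross-check; closed-form
second-moment expressions via hypergeometric functions are not used (we
could not validate them against hand sums).

## Estimation

The untruncated log-likelihood separates in (β₁, β₂): β₁ is an ordinary
Poisson regression of y₁ on X, and β₂ a Poisson regression of y₂ on X with
offset ln y₁ over the rows with y₁ > 0 (rows with y₁ = 0 contribute no
information about β₂ and are retained in the β₁ part — no ad-hoc
exclusion). Both stages use IRLS (statsmodels GLM).

The truncated likelihood adds Σᵢ ln c₁ᵢ + ln c₂ᵢ and no longer separates
cleanly; it is maximized by L-BFGS starting from the untruncated
estimates, with the exact score

d lnL/dβ₁ = X′(y₁ − μ̃₁),  d lnL/dβ₂ = X′(y₂ − μ̃₂),

where μ̃ are the truncated means — the standard truncated-Poisson score
generalizes directly because d ln P(Y≤k; λ)/dλ = μ̃/λ − 1. Convergence
tolerances: relative objective change 1e−12, projected gradient 1e−7,
at most 500 iterations; non-convergence is flagged on the result, never
silent. If truncation bounds are not supplied at fit time they default to
the observed maxima and are recorded in the result.

Standard errors come from the inverse of the numerically differentiated
observed information at the optimum (central differences, per-parameter
step), for both variants; z-values use the standard normal reference,
two-sided.

Numerical notes. All pmfs are evaluated in log space. The truncated
log-likelihood is computed as a sum of truncated Poisson log-pmfs in a
form where the −λ term common to the pmf and its normalizer is cancelled
*analytically* (weights j·ln λ − ln j!, logsumexp-normalized): computing
"untruncated terms + ln c" as two separate floats loses all precision once
λ exceeds ~10¹⁶, which line-search trial steps can reach on raw-scale
covariates. Truncated-moment weights are max-shifted for the same reason.

## Dispersion and adjusted inference

Each part gets a Pearson moment estimator
φ̂ᵣ = 1/(n−p) Σ (yᵣᵢ − μ̂ᵣᵢ)²/V̂ᵣᵢ, with p the number of fitted
coefficients of that part (intercept included) and, for the conditional
part, the sum running over rows with y₁ > 0 (n is then the count of those
rows). Under the truncated variant μ̂ and V̂ are the direct
truncated-summation moments. The correction-factor route
(δ = −λα, α = h(k,λ)/H(k,λ), V = λ − δ(μ−k−1)) is available as
`trunc_corrected_mv` and agrees with summation to 1e−8; note α uses the
retained mass H, not the truncated-away tail.

Adjusted inference scales each block's standard errors by √φ̂ᵣ, so
underdispersion (φ̂ < 1) tightens them.

## Grouped fit statistics T1 and T2

Observations are grouped by the distinct observed y₁ values. For group g
the 2-vector of deviations — (ȳ₁ − mean fitted marginal mean,
ȳ₂|g − mean fitted conditional mean) — enters a diagonal quadratic form
with fitted-variance denominators; T1 is the sum over groups, nominally
chi-square with 2 df per group (1 for the y₁ = 0 group, whose conditional
component is degenerate and skipped; empty groups simply do not appear).
T2 is the same form with dispersion-scaled means μ* = φ̂μ̂ and
variance denominators; at φ̂₁ = φ̂₂ = 1 it equals T1 identically.

Two denominator conventions are exposed:

- `per_observation` (default): the group-average fitted variance
  Σ V̂ᵢ / n_g. T1 is then an O(1) descriptive index whose magnitude is
  stable in n.
- `group_mean`: the variance of the group mean, Σ V̂ᵢ / n_g². The
  conditional components are then correctly scaled for a group-mean
  comparison, but the statistic as a whole grows proportionally to n.

**Calibration caveat (important).** Because the grouping variable is the
outcome itself, the marginal deviation g − mean(λ̂₁ᵢ | y₁ = g) has a bias
that does not vanish with n (the average fitted rate within the group
selected by Y₁ = g is not g). Simulation under the correct model shows the
consequence directly: at n = 3000 the per-observation form rejects the
nominal χ² reference essentially always, and the group-mean form produces
statistics of order n. Neither convention yields a calibrated χ² test, and
we deliberately do not alter the statistic's definition to force
calibration. Treat T1/T2 as *descriptive* fit indices (smaller is better,
compare across models on the same data) rather than as exact tests; the
likelihood-ratio test, which is correctly calibrated (verified by
simulation), is the inferential tool of choice here. The conditional
components under the `group_mean` convention are the statistically
well-behaved ingredient and are what give the statistic its power against
conditional-mean misspecification.

## Model comparison

- Likelihood-ratio test of all slopes: −2(lnL₀ − lnL), χ² with 2p df
  (p slope covariates per part). Null calibration verified by simulation
  (rejection rate at α = 0.05 inside the binomial 99% band over 500
  replications at n = 3000).
- Vuong non-nested comparison: mᵢ = ln f(y₁ᵢ,y₂ᵢ) − ln g(y₁ᵢ,y₂ᵢ) at the
  two fitted models; raw V = Σmᵢ/(√n·sd(m)). The adjusted statistic
  subtracts the Schwarz complexity term ((p_f − p_g)/2)·ln n from the
  numerator (inert when both models have the same number of parameters,
  as in truncated-vs-untruncated on a shared design). |V| > 1.96 favors
  the numerator (positive) or denominator (negative) model; identical
  densities are reported as a degenerate comparison, not a division by
  zero.

## Synthetic data

`bivpois.synthetic` draws covariates per column law (bernoulli, uniform,
normal), forms λ₁, λ₂ through the log links, and samples the pair by the
model's own generative story — inverse-cdf on the finite support for the
truncated variant (exact, no rejection). Continuous age-like covariates
can be standardized internally before the coefficients apply (the raw
column is what is written to CSV; the standardization constants are
recorded in the truth sidecar). Departure modes: `("negbin", v)` replaces
conditional draws by gamma-mixed Poisson with matched mean and variance
v× mean; `independent_y2` makes the conditional mean exp(x′β₂) unrelated
to y₁ for rows with y₁ > 0 (rows with y₁ = 0 keep y₂ = 0, so the dataset
remains representable by the model's support).

Named scenarios (`scenario_suite()`) fix the study conditions used
throughout the tests:

- `well_specified`: one standard-normal covariate, β₁ = (0.5, −0.3),
  β₂ = (−0.2, 0.4).
- `truncated`: same, truncated at (k₁=8, k₂=10) — truncation barely binds.
- `truncated_tight`: β₁ = (1.0, 0.2), β₂ = (−0.2, 0.2), bounds (5, 6) —
  5–10% of the untruncated mass lies beyond each bound, so the truncated
  and untruncated variants are genuinely distinguishable; this is the
  condition for the model-selection and truncated-recovery studies.
- `overdispersed`: conditional variance twice the mean.
- `independent`: conditional mean unrelated to Y₁.
- `hrs_shaped`: n = 5568 with binary gender (p=.40), Hispanic race
  (p=.10), veteran status (p=.25) and uniform age 50–90 (standardized
  internally); intercepts set so E Y₁ ≈ 2.6 and E Y₂ ≈ 0.77, slope
  magnitudes in the range reported for comparable health-survey analyses.

What the generator does **not** emulate: covariate dependence between
columns, measurement error, informative missingness, zero inflation, or
any dependence between Y₁ and Y₂ beyond the conditional-rate mechanism.
Passing recovery/calibration tests on these scenarios therefore
demonstrates correctness of the estimator and tests under the model's own
assumptions, not robustness on messy observational data.

Study sizes used by the test suite: parameter recovery at n = 5000;
null calibration with 500 replications at n = 3000; model selection with
100 replications at n = 3000; overdispersion detection with 200
replications at n = 1000. These sizes give Monte-Carlo error comfortably
inside the asserted bands.

## Known limitations

- The correlation standard-error formula is implemented verbatim from its
  printed source, whose bracket placement is ambiguous; we cube the whole
  braced denominator. The resulting value is tiny for any realistic n
  either way, but users comparing against other software should check the
  convention.
- T1/T2 are not calibrated χ² tests (see above).
- One shared design matrix for both parts; no offsets/exposure,
  alternative links, regularization, or missing-data handling.
- The conditional truncation bound k₂ is global, not per-y₁ level.
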