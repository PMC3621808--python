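# Methods

## Scientific setting

`sportmed` implements a mediation analysis of the kind used in large
school-based surveys of children's physical activity: does the *family
environment* (equipment at home; parental financial, logistic and emotional
support; reinforcement; parental modelling; co-participation) influence a
child's weekly sports participation directly, or indirectly through the
child's own *cognitions* (attitude, health beliefs, enjoyment, perceived
behavioural control)?  The dual-process EnRG framework motivates testing
both channels: an unmediated, more automatic environment-to-behaviour path,
and a path through deliberate cognition.

The data layout is a three-level hierarchy — children within schools within
countries — with a binary outcome (participation in at least 30 min/week of
sport), seven exposures on their survey grids, four mediators on a
five-point scale coded −2..2, and the covariates sex, age and parental
education.  Because the underlying multi-country survey data are not
publicly deposited, the package ships a synthetic cohort generator with
fully known truth; all statistical validation runs against that truth, and
the published estimates enter only as worked-example inputs and arithmetic
identity checks.

## Mediation model

For one exposure X, mediators M_1..M_k, outcome Y and covariates Z, all
models carry random intercepts for school (nested in country) and country:

* total effect: logit P(Y=1) = c·X + γ'Z + u_country + u_school
* a-paths:      M_i = a_i·X + γ_i'Z + u_country + u_school + ε  (one linear
  model per mediator)
* b-paths and direct effect: logit P(Y=1) = Σ b_i·M_i + c′·X + γ'Z + u's
  (single-mediator models use one M at a time; the multiple-mediator model
  includes every mediator whose single-model indirect effect is
  significant)

Indirect effects are products of coefficients, a_i·b_i, on the log-odds
scale.  Single-model significance uses Sobel's first-order SE,
√(a²·SE_b² + b²·SE_a²), with the fixed normal quantile 1.959964.  The total
indirect effect Σ a_i·b_i uses the multivariate delta-method variance

    Σ_i (a_i²·Var(b_i) + b_i²·Var(a_i)) + Σ_{i≠j} a_i·a_j·Cov(b_i, b_j),

with Cov(b_i, b_j) taken from the joint outcome fit.  The a-paths come from
separate models and are treated as independent (Cov(a_i, a_j) = 0); an
optional argument accepts a user-supplied a-covariance.  A parametric
Monte-Carlo resampler of Σ a_i*·b_i* is provided as a clearly non-canonical
validation alternative; the delta-method CI is the reported one.  The
first-order delta method drops the Var(a)·Var(b) term of the exact product
variance, so its quoted 2% agreement with simulation holds in the regime
where every relative SE is below ~25% — the regime of the published
estimates — and degrades as effects approach zero.

Percent mediated divides each a_i·b_i (and their sum) by (c′ + Σ a_i·b_i),
×100, so the per-mediator percentages sum to the total by construction.
Classification: *inconsistent* when the significant total indirect effect
opposes the sign of c′ (suppression; percentages are then reported as
suppressed, since the decomposition has no interpretation), *partial* when
total and direct are both significant with the same sign, *full* when only
the indirect is significant, *none* otherwise.  Percentages are also
suppressed when |c′ + Σ a_i·b_i| falls below a configurable floor (default
0.01 on the log-odds scale), where the ratio explodes.

## Three-level model estimation

Linear (identity-link) models are fitted by maximum likelihood through
statsmodels' `MixedLM`, with country as the top grouping factor and school
as a variance component nested within it (composite `country:school` keys
prevent accidental crossing).

No maintained Python package fits frequentist logistic mixed models, so the
logistic branch is implemented in-package with the Laplace approximation.
Random intercepts are standardized (u = σ·z), an inner Newton iteration
maximizes the penalized log-likelihood over z at fixed (β, σ_country,
σ_school), and L-BFGS-B maximizes the Laplace objective
ℓ(β, σ) = g(ẑ) − ½·log|H_zz| over fixed effects and both SDs jointly,
warm-started from the cheaper jointly-profiled mode.  Internally the
design is standardized (centred/scaled columns) to remove the flat
intercept/covariate ridge, and estimates are transformed back.  The
fixed-effect covariance is the β-block of the inverse penalized Hessian at
the optimum — the same conditional covariance lme4 reports.  Optimizer
settings: relative objective tolerance 1e-8 for the inner Newton, 1e-11
for the outer, at most 200 iterations, SDs bounded in [0, 5]; all
configurable.  Non-convergence raises an error carrying the optimizer
status, and rank-deficient designs raise an error naming the collinear
columns.

An optional nested adaptive Gauss–Hermite refinement (`method="agq"`,
default 7 points per level) integrates school effects with adaptive GH
inside each country node and the country effect around its Laplace mode; on
cohorts of a few hundred children it moves coefficients by well under 1%,
which is why Laplace is the default.  On a seed-locked fixture cohort the
Laplace fit agrees with lme4's `glmer` to better than 0.1% on every
coefficient (and slightly exceeds its log-likelihood); the linear branch
matches `lmer` ML to ~1e-5.  Exact numeric equality with any particular
mixed-model implementation beyond that is not a goal: estimation settings
differ across tools in the third decimal.

Variance components of binary-outcome models sit on the boundary with
appreciable probability: when the between-cluster dispersion does not
exceed its binomial expectation the ML estimates collapse to zero and the
fit degenerates exactly to single-level logistic regression (a property
used as a test oracle); on other realizations small positive estimates
appear by sampling noise and the fits legitimately differ.

## Synthetic cohort generator

The generator emulates the survey's structure, not any real country's
idiosyncrasies: 7 countries × 25 schools × 28 children by default
(n = 4900, near the real analytic sample), exposures drawn as truncated
normals snapped to each instrument's response grid, mediators as latent
linear predictors (exposure effects + sex effect + school and country
intercepts + Gaussian residual) rounded and clipped to the five-point grid,
and the outcome as a Bernoulli draw from a logistic model on the *observed*
(gridded) mediators.  Sport hours among participants are a truncated normal
on [0.5, 10] snapped to the half-hour grid, so participation ⇔ hours ≥ 0.5
holds by construction.  Missingness is independent per column at a
configurable rate (default 2% on parent-reported columns in the default
truth), emulating item non-response but not the real study's missingness
mechanism.

Calibration happens at truth-construction time, never against test
outcomes: latent (μ, σ) of each gridded variable are solved so the
*observed* marginal mean (weighted heavily) and SD match the published
descriptives — some published (mean, SD) pairs are unattainable for a
snapped truncated normal, and the compromise favours the mean — and the
outcome intercept is solved from a logit-normal moment approximation
(E[expit(N(μ, s²))] ≈ expit(μ/√(1+k²s²)), k = 16√3/15π) to hit the 53.4%
participation target.  Random-intercept SDs default to ICCs of roughly
3% (country) and 5% (school) of the relevant total variance; the source
study reports no variance components, so these are plausible survey-scale
values, stated here as the package's own choice.

One root seed drives everything; each column and random-effect level draws
from a named substream (`[seed, crc32(name)]`), so adding a column never
perturbs existing ones, and a fixed (truth, seed) pair is byte-reproducible.

Default path coefficients mirror the published estimates' order of
magnitude (a-paths 0.006–0.09, b-paths the logs of the published
multiple-model ORs, c′-paths the logs of the published direct ORs).  They
are chosen for testability; no claim is made that they estimate the real
study's generative truth.

### Discretization attenuation and the calibration truth

Rounding-then-clipping a latent Gaussian onto the five-point grid is a step
function with unit jumps at −1.5, −0.5, 0.5, 1.5 (anything beyond ±1.5
lands in an end category).  By Stein's lemma the regression slope of the
observed mediator on an (approximately Gaussian) exposure is the latent
slope times Σ_k φ(k; μ_lat, σ_lat) over those cutpoints — about 0.93 at the
calibration truth's latent SD, and much smaller near the scale ends (the
published attitude marginal, mean 1.9 and SD 0.4 on a −2..2 scale, sits
almost entirely in the top category, so latent effects on it are heavily
attenuated in any analysis, real or synthetic).  The fitted a-models target
the observable slope, so calibration studies compare estimates against the
*observable* indirect effects (`true_mediated_effects(..., observable=True)`);
comparing against latent products would conflate estimator calibration
with ordinal-measurement attenuation.

The documented calibration truth (`recovery_truth`) therefore centres the
mediators (target mean 0, SD 1.1) and uses one active exposure (financial
support) with a-paths 0.12–0.18 and b-paths 0.10–0.60, giving observable
indirect effects up to ~0.10 — large enough for relative-error statements —
at 7 countries × 10 schools × 43 children (n = 3010).  The null truth
(`null_truth`) zeroes every a-path and keeps the b-paths, so the indirect
channel vanishes while the outcome model stays informative.

## Validation studies and problem sizes

The shipped studies (also recomputed by `scripts/acceptance.py`) use:

* delta-method vs Monte Carlo: 100,000 parametric draws per randomized
  admissible input set;
* single-level degeneracy: n = 2016 (7×4×72) zero-variance cohorts;
* parameter recovery: 50 cohorts of n = 3010; mean estimated a_i·b_i lands
  within a few percent of the observable truth, and the delta CI covers the
  observable total in ≈95% of replicates;
* null calibration: 200 cohorts of n = 1400 (7×10×20); the total-mediated
  CI excludes zero at roughly the nominal one-sided-per-tail rate.  The
  product-of-coefficients CI is known to be conservative near the complete
  null, so rates modestly below 5% are expected behaviour, not a defect.

These sizes are the package's validation design: large enough for stable
rates, small enough to run routinely on one CPU.

## What passing tests do and do not show

The generator draws exposures independently of each other and of the
covariates, uses a single shared random-intercept SD across mediators, and
applies missingness completely at random.  Real survey data have correlated
exposures, country-specific response styles, informative missingness and
single-item measurement error beyond grid rounding.  Passing validation
therefore shows that the estimators and interval procedures are calibrated
under a faithful *structural* emulation of the design (nesting, grids,
marginals, prevalence), not that any substantive conclusion transfers to
real cohorts.

## Known limitations

* Random slopes, crossed random effects, survey weights and imputation are
  out of scope; the analysis is complete-case by design.
* The a-paths' independence assumption ignores the (typically small)
  correlation induced by fitting mediator models on the same children.
* Laplace fixed effects for binary outcomes carry O(1/cluster-size) bias;
  at the default cluster sizes this is ≲1–2% and the AGQ option exists for
  verification.
* Percent mediated is a ratio of log-odds quantities; it is reported to
  mirror the field's convention but is unstable whenever the direct and
  indirect effects nearly cancel, which is exactly when it is suppressed.
* No multiple-testing correction is applied across the seven exposures,
  matching the analytic convention of the source design.
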