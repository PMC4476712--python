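# Methods

## The estimation problem

A county's observed health outcome — a death count over a small population,
a survey mean over a few dozen respondents, a proportion of births — is a
noisy measurement of its latent health level, and the noise varies by
orders of magnitude across counties. Ranking counties on the raw
observations therefore mostly ranks their noise. The package treats the
latent county levels as random effects nested in states, estimates the
population structure by maximum likelihood, and propagates the remaining
uncertainty into the ranks themselves.

## Model classes and their assumptions

All four designs share the nesting: a state block and a county block of
random effects, mutually independent across units, Gaussian with
level-specific covariances estimated from the data.

**Cross-sectional.** One observation per county; linear predictor
`β₀ + e_k + e_jk` under a Poisson (log link, population offset), binomial
(logit link) or known-variance normal likelihood. The normal case models
the *log* of an observed survey mean with sampling variance fixed at the
delta-method transform `(se/m)²` of the reported natural-scale standard
error; the CLT justifies normality of the county mean regardless of the
respondent-level distribution.

**Longitudinal.** Poisson counts over `t = −3..0`, with correlated
(intercept, slope) pairs at both levels. Anchoring the intercept at `t = 0`
makes the intercept — and each EB intercept — the current-period log rate,
which is the quantity ranked. Assumes log-linear trends and, conditional on
the county's line, independent Poisson noise per period.

**Joint age-group.** Nine age-specific rates in one period; a shared random
intercept per level plus an independent random slope per non-reference age
group (no cross-age correlations; the covariance is diagonal). The shared
intercept is what lets sparse age groups borrow strength from the county's
overall mortality level.

**Joint bivariate.** Two measures, indicator-coded (`i = 0` reference,
`i = 1` contrast), with correlated (intercept, contrast) random pairs per
level. The contrast parametrization means measure 1's county deviation is
the *sum* `a_jk + b_jk`; cross-measure independence therefore corresponds
to `σ² + ρστ = 0`, i.e. a strongly negative ρ, not ρ = 0 (this matters for
the "unrelated measures" study below). Binomial fits convert survey
proportions to effective sample sizes `n = p(1−p)/se²`, rounded to the
nearest integer with a floor of 1, and a pseudo-numerator `round(p·n)` —
a binomial likelihood needs integers and the rounding error is far below
sampling noise.

## Estimation

Maximum likelihood (not REML) throughout, with a Laplace approximation to
the marginal likelihood for Poisson and binomial families; for the
known-variance normal family the same code path is exact because the
integrand is Gaussian. The random-effect modes are found by a damped
Newton solver on the penalized joint log-density, exploiting the arrowhead
sparsity of its Hessian: counties are conditionally independent given
their state, so each Newton step factorizes per state by a Schur
complement over the county blocks (cost linear in counties, cubic only in
the small block dimension, at most 9).

The outer optimization runs a quasi-Newton (L-BFGS-B) search over the
unconstrained parameterization — fixed effects, log-SDs, atanh
correlations — which keeps variance estimates nonnegative and correlations
in (−1, 1) by construction; log-SDs are bounded in [−7, 3] so a variance
collapsing to zero lands at an explicit floor (~10⁻⁶) instead of
overflowing. Because quasi-Newton iterations stall on shallow, noisy
finite-difference surfaces, a Newton polish with central-difference
gradient and Hessian refines the optimum for models with up to 12
parameters; convergence is declared on the Newton decrement
(`g'H⁻¹g/2 < 10⁻⁵·(1+|ℓ|)`), with bound-pinned directions projected out of
the gradient, and a restart-from-perturbation fallback otherwise. The
fixed-effect covariance is the inverse observed information of the Laplace
likelihood in β with variance parameters held at their estimates — the
empirical-Bayes convention, which deliberately ignores variance-parameter
uncertainty.

Suppressed records contribute nothing to the likelihood. A county with no
active records keeps an EB block equal to the prior (mean zero, covariance
the estimated variance components), so the roster survives and such
counties can still be ranked, with appropriately wide uncertainty.

## Posterior draws and YPLL-75

Draws follow the conditional-independence recipe: fixed effects from
`MVN(β̂, cov(β̂))`, each state and each county block independently from its
EB conditional normal, all mutually independent. The linear predictor is
assembled at the design's reference point (t = 0; each age; each measure)
and inverse-linked. The default draw count is D = 1000, configurable; the
acceptance studies use 300–600 where only means and tail fractions are
needed. This understates uncertainty relative to a fully Bayesian
treatment (no variance-component uncertainty, no posterior dependence
between a state and its counties); that is the cost of the empirical-Bayes
design, not an implementation shortcut.

YPLL-75 per 100,000 combines the nine age-specific rate draws as
`10⁵ · Σ_a ρ_a n_a w_a / Σ_a n_a` with weights `w = (74.5, 72, 65, 55, 45,
35, 25, 15, 5)` — 75 minus the midpoint of the age intervals [0,1), [1,5),
[5,15), …, [65,75). Midpoint weighting is the standard convention; a
life-table variant would change w by well under a year per group.
Age-group populations come from the panel's current-period denominators.

## Ranking

Within each draw, counties are ranked ascending on health-adverse measures
(rank 1 = healthiest). Ties have probability zero for continuous draws;
if duplicated inputs create them, column (roster) order breaks them
deterministically so every draw is an exact permutation. Point ranks are
the ranks of posterior mean ranks, which minimizes squared error loss over
the posterior rank distribution (verified against exhaustive search in the
tests). National quartiles cut the point ranks at `ceil(C·q/4)`, so sizes
differ by at most one; quartile 1 is healthiest. A county's certainty
class comes from the fraction of draws in which its rank lands in its
assigned quartile's interval: low (< 0.50), medium (0.50–0.75), high
(≥ 0.75).

## Posterior predictive checks

Replicate datasets redraw each county's outcome from its sampling model at
each posterior draw — `Poisson(ρ_d·n)/n`, `Binomial(n, π_d)/n`, or
`Normal(log μ_d, s²)` — with the county's actual denominators and known
variances. Because mean structure replicates even under misspecification,
the compared statistics are the inter-quartile range (linear-interpolation
quantiles, the numpy default) and the adjusted Fisher–Pearson skewness
`g₁·√(n(n−1))/(n−2)`. The p-value is two-sided,
`2·min(Pr(T_rep ≥ T_obs), Pr(T_rep ≤ T_obs))` with ties counted in both
tails and capped at 1 — both over- and under-dispersion are misfits.
`p < 0.05` is flagged as poor fit.

Two check granularities exist. `run_ppc` compares the cross-county vector
of one measure at the reference point. `run_panel_ppc` replicates *every*
cell of a counts panel (all counties × periods from one joint posterior
sample) and compares the full cell-rate vector; this is the strictest
dispersion check, because within-county noise that the model's two latent
degrees of freedom per county cannot express has nowhere to hide. The
misfit study uses the panel check: per-record negative-binomial
overdispersion (gamma-mixed Poisson, dispersion shape 2, count variance
μ + μ²/2) is invisible to the one-record-per-county check — a mixed
Poisson with a free county variance simply absorbs it, and EB conditioning
makes the p-value conservative — but is detected nearly always by the
panel check.

## The synthetic-data generator

Generators draw from exactly the models the fitters estimate, plus
reporting noise, and return latent truth for recovery tests. Defaults are
the fitted values of the real county health application (infant mortality
log-rate intercept −5.01, trend −0.02, county/state intercept variances
0.044/0.038, slope variances 0.0017/0.0004, correlations 0.355/0.728; the
analogous sets for the age-group, health-days and prevalence models), so
synthetic panels have realistic scale. County populations are log-uniform
over 10^2.5–10^6 — this range creates the small-county sparsity the
method targets — split across age groups by a fixed national age
distribution. Survey log-scale SEs are log-uniform over [0.02, 0.3], and
respondent counts log-uniform over [50, 3000], mimicking heterogeneous
county sample sizes.

What the generator does not emulate: spatial correlation between
neighboring counties, real county population sizes, non-Gaussian random
effects, reporting-system artifacts, or covariate structure. Passing
recovery and precision tests on these panels shows the machinery is
correct and calibrated under the model's own assumptions — not that the
model is adequate for any particular real surveillance dataset; the
posterior predictive checks are the tool for that question.

Suppression rules mirror vital-statistics and survey practice: counts of
five or fewer events are suppressed, survey records with fewer than 50
respondents or a nominal 95% CI (z = 1.96) wider than 20% of the point
estimate are censored. Records are flagged, never deleted. With the
default SE range a majority of synthetic survey records fail the 20% rule
— the generator's SEs are deliberately heavier-tailed than real BRFSS
county estimates so that censoring paths get exercised.

## Study sizes and numerical tolerances

The replicate studies run at sizes chosen to give clear answers in minutes
on one CPU: parameter recovery uses 30 panels of 51 states × 24 counties
(the bias criterion is 3 Monte-Carlo SEs of the study's own replicate
mean, so the band adapts to the size); the trend-precision comparison 20
replicates of 20 × 15 counties with populations 10³–10^4.5 (small enough
that a single period ranks poorly); the unrelated-measures comparison 20
replicates at the prevalence-pair fitted values; the misfit study 120
replicate pairs of 20 × 15 counties. Oracle agreements are checked at
10⁻⁶ (exact Gaussian ML, where both routes optimize the same exact
likelihood) and 10⁻² (Laplace vs adaptive-quadrature Poisson ML, where the
approximation itself contributes the gap).

## Known limitations

* Laplace accuracy degrades for very small counts (expected events ≪ 1 per
  cell); the joint age-group model inherits this in the youngest groups.
* No negative-binomial or zero-inflated families; overdispersion is
  detected (by the checks) but not modeled.
* Random effects are strictly nested; no spatial or crossed structure.
* Variance-component uncertainty is not propagated into the draws.
* The outer optimizer's finite-difference derivatives set a practical
  accuracy floor of roughly 10⁻⁶–10⁻⁷ on parameter estimates.
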