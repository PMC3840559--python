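# Methods

## The model

`lexpit` fits the linear-expit (lexpit) model for the absolute risk of a
binary outcome within a fixed risk period τ:

    R(x, z) = β′x + expit(γ₀ + γ′z),        expit(u) = eᵘ / (1 + eᵘ)

The additive block contributes risk differences: each βₖ is the change in
absolute risk (probability units) per unit of xₖ, adjusted for everything
else in the model. The multiplicative block acts on the *residual* risk
R − β′x through a logistic link: each exp(γₖ) is a residual odds ratio, the
odds-ratio effect of zₖ on the risk remaining after the additive component
is subtracted. The baseline risk R₀ = expit(γ₀) sits inside the expit so it
needs no constraint of its own. Setting β = 0 recovers ordinary logistic
regression; an empty multiplicative block recovers the binomial linear
model. Risks divide by τ to give average incidence rates under a
constant-risk assumption.

Continuous multiplicative covariates may be centered (e.g. age at 60) so
that R₀ refers to a stated reference profile; additive covariates may be
rescaled (e.g. pack-years per 10) so β is reported per a conventional unit.
Both are explicit per-covariate settings in `LexpitSpec`, never automatic.

## Case–control weighting

In a population-based case–control study with complete case ascertainment
and within-stratum simple random sampling of controls, expansion weights

    w = 1 for cases,      w = N_j / n_j for controls of stratum j

project the sample onto its study base: the weighted control count of
stratum j equals N_j exactly. The two-stratum worked example in the README
(and the acceptance script) is precisely this computation: with 1,537 male
cases and 1,617 male controls expanded by 774,221/1,617 ≈ 479, the fitted
male 3-year risk is 1,537/(1,537 + 774,221) ≈ 2.0 per 1,000.

Weights may instead be supplied as an explicit column (taking precedence
over a design, with a warning) for designs whose sampling fractions come
from elsewhere, and an optional case-weight column relaxes the
complete-ascertainment assumption.

## Estimation

Estimates maximize the expansion-weighted Bernoulli pseudo-log-likelihood

    l(Θ) = Σ_j Σ_i w_ij [ y_ij log R_ij + (1 − y_ij) log(1 − R_ij) ]

subject to the feasible region F: 0 ≤ R(x, z) ≤ 1 at every *unique
observed* covariate pattern (duplicates collapsed after centering/scaling).
With unit weights this is the exact cohort likelihood.

The optimizer is sequential quadratic programming (SLSQP) over the full
parameter vector Θ = (β, γ₀, γ) with one vectorized constraint pair per
pattern, using analytic gradients of both objective and constraints. The
objective is normalized by the total weight for conditioning. Starting
values take γ from a weighted logistic fit of the multiplicative block with
β = 0 — a point always interior to F. When no constraint is active at the
SLSQP solution, a damped Newton polish (analytic observed information,
backtracking that keeps every observation and pattern risk strictly inside
(0, 1)) refines the interior optimum to near machine precision; this is
what lets the special cases agree with closed-form proportions and the
weighted-logistic MLE to ~1e-8 rather than solver tolerance.

Numerical choices: risks are clipped at 1e-12 inside the smooth surrogate
objective (the public likelihood function returns −∞ outside (0, 1));
constraint tolerance 1e-8; iteration cap 500; convergence at an interior
optimum requires the per-unit-weight gradient below 1e-6, and at a boundary
optimum defers to the SQP KKT test, with a warning that Wald inference for
boundary parameters is unreliable. The fit never returns a point worse than
its start, is deterministic, and is invariant to row order and to rescaling
all weights by a constant. Covariates constant across the sample are
rejected by name; strata contributing controls but no cases are allowed.

## Variance

Because l is a pseudo-likelihood, the inverse information is not a valid
covariance. Influence-function linearization is used instead: each
observation's influence is d_ij = w_ij Ĥ⁻¹ s_ij with s_ij the
per-observation score and Ĥ the weighted observed information (so the
influences sum to zero at an interior optimum, and the covariance is
invariant to weight rescaling). The parameter covariance is the estimated
variance of the influence total under the study's two randomness sources:

* **controls** — within-stratum SRS, estimated by the usual
  with-replacement stratified form n_j/(n_j−1) Σᵢ (d − d̄)(d − d̄)′;
  single-unit strata are collapsed with their neighbour by label order, and
  an optional finite-population correction (1 − n_j/N_j) is available but
  off by default (census-scale fractions are tiny);
* **cases** — a census of a random disease process. The case stratum
  therefore contributes the *uncentered* sum Σ d d′ (Poisson /
  superpopulation treatment). A centered case stratum would capture
  case-mix variation only: on the gender-only scenario it understates the
  Monte-Carlo SD of the risk difference by ~22%, while the uncentered form
  tracks it within 2%. The centered variant is retained as an option
  (`case_strategy="centered"`), and is also what a fixed-size case
  bootstrap estimates.

A stratified bootstrap (`bootstrap_covariance`) provides an independent
cross-check: controls are resampled with replacement within strata, cases
with Poisson(1) multiplicities so that both routes estimate the same
target; replicates are refit warm-started at the estimate.

Wald intervals are estimate ± z·SE; residual-odds-ratio intervals
exponentiate the γ endpoints.

## Diagnostics

The weighted Hosmer–Lemeshow statistic ranks observations by fitted risk
and partitions them into groups (default 10) of near-equal *total weight* —
not equal count, because weights span three orders of magnitude between
cases and expanded controls. With O_g, E_g, W_g the weighted observed
events, expected events and group weight,

    X² = Σ_g (O_g − E_g)² / (E_g (1 − E_g / W_g)),

which reduces to the classical statistic when all weights are 1. Groups
with degenerate expectations merge with a neighbour. No p-value is
attached: under expansion weighting the reference distribution is
nonstandard, and the statistic is used comparatively (lower = better
calibrated), which is how it behaves in the test suite's
true-vs-misspecified simulations.

The risk-exposure scatter reports crude weighted risk by equal-weight
exposure bin; a straight-line profile suggests an additive effect,
exponential curvature a multiplicative one. The dual-scale comparison fits
an exposure additively, multiplicatively, and on both scales jointly
(`allow_dual=True`; the joint model is often weakly identified, which is
why dual membership is otherwise rejected), reporting coefficients, Wald z
and goodness of fit side by side without an automatic verdict.

## Synthetic data

The generator draws a finite study base stratum by stratum, covariates from
stratum-specific distributions, disease as an independent Bernoulli draw
from a known lexpit-form risk (configurations implying a risk outside
[0, 1] are rejected before simulation), then takes every case and a
within-stratum SRS of controls from the non-cases. The emitted design
records N_j as the full stratum population (census-frame convention, where
the frame predates case occurrence; `count_basis="non_cases"` is available,
and with risks of ~2 per 1,000 the difference is negligible).

The default scenario mirrors a Lombardy lung-cancer case–control frame: 90
strata (2 genders × 9 age bands × 5 regions) with the frame's census
populations (~1.63 M persons) and per-stratum control allocations (2,116
controls), and truth

* additive: female +4.6e-5, pack-years +52.9e-5 per 10, female×pack-years
  −39.3e-5 (3-year risks);
* multiplicative: residual OR 1.12 per year of age, centered at 60;
* baseline 3-year risk expit(γ₀) = 2e-4; ever-smoking prevalence 0.75
  (men) / 0.43 (women); pack-years among smokers ~ Gamma(1.5, 18) capped
  at 120.

The free values (baseline risk, prevalences, pack-year law) were fixed once
to yield a realistic ~1,500–2,000 cases per draw. A two-stratum gender-only
scenario reproduces the worked example's risks (≈2.0 and ≈0.5 per 1,000).

What the generator does *not* emulate: interview nonresponse (treated as
non-informative), secondary-base control sources, measurement error in
smoking history, and correlation between covariates beyond the
gender/age/region structure. Passing recovery and coverage tests therefore
demonstrates correctness of the estimation machinery under the stated
sampling model, not robustness to those real-data complications.

One bookkeeping note: the published female frame is internally inconsistent
by 5,732 persons in one regional column (its cells exceed the printed
margin by exactly the oldest age cell). The package keeps the printed cells
for the 90-stratum frame and the printed gender margins (774,221 / 851,550)
for the worked example; the discrepancy is asserted explicitly in the test
suite.

## Problem sizes used in the test suite

Stochastic checks run at fixed seeds with sizes chosen to keep the default
suite a few minutes long on one core: 200 replicates of the full-scale
90-stratum scenario for recovery/coverage; 500 replicates of the gender
design at one-tenth population scale for SE-vs-Monte-Carlo calibration;
2,000 bootstrap draws on one ~900-row dataset for the
bootstrap-vs-linearization check; 200 replicates of a 30,000-person
two-stratum population for the goodness-of-fit ordering.

## Known limitations

* **Small-stratum finite-sample bias.** With the frame's real control
  allocation, many strata sample only 1–5 controls. The weighted score
  totals are unbiased (linear in the weights), but the nonlinear solve
  inherits an O(Var) bias from the noisy expanded totals: on the default
  scenario the additive coefficients are overestimated by roughly 1%
  (e.g. +5.8e-6 on the pack-years coefficient across 600 replicates), and
  the suite's unbiasedness check at 200 replicates is powerful enough to
  detect this real effect. Inflating every stratum's control sample
  tenfold removes it. Interval coverage is unaffected (~94–95% pooled).
* Boundary optima: when feasibility constraints are active, Wald inference
  for the pinned parameters is unreliable (warned, not corrected).
* The incidence-rate conversion is exactly R/τ; no competing risks, no
  within-period risk variation.
* No conditional likelihood for individually matched sets, no
  post-stratification or calibration weighting, no penalized variants.
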