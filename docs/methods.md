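# Methods

## The model

`mimicgsem` fits a generalized structural equation model of the MIMIC
(multiple-indicators, multiple-causes) type for child malnutrition and
morbidity. Two latent endogenous traits, malnutrition (η₁) and morbidity
(η₂), are measured by six binary indicators — stunting, wasting and
underweight for η₁; diarrhea, cough and fever for η₂ — and caused by measured
child, maternal and household covariates:

    η₁ = b₁′x + ζ₁
    η₂ = b₂′x + β η₁ + ζ₂
    P(y_j = 1 | η, x) = g⁻¹( α_j + λ_j η_parent(j) + γ_j′ x_direct )

with g one of logit, probit or complementary log–log, ζ ~ N(0, Σ_v) the
latent disturbances, and child sex and age group entering the indicators
directly. In general the package supports any acyclic latent graph
η = B_η η + B_x x + L v with v standard normal and Σ_v = LL′.

Model assumptions worth stating plainly:

- Conditional on the latent vector, the six indicators are independent
  Bernoulli draws (local independence).
- Latent disturbances are Gaussian; this is what makes Gauss–Hermite
  integration the right tool, and it is an assumption of the model, not a
  verified property of any survey population.
- Covariates are treated as measured without error and enter through
  treatment (dummy) coding against declared reference levels.
- Each child contributes an independent draw of the latent vector: the unit
  of clustering is the child, not a survey sampling cluster. Survey design
  features (two-stage sampling, strata, weights) are out of scope.

## Identification

The anchor-loading convention: the first indicator declared for each latent
has its loading fixed at 1 (stunting and diarrhea in the study model), latent
intercepts are fixed at 0, and the disturbance variances are free. The
disturbance covariance is diagonal by default: with a structural η₁ → η₂ path
*and* a free disturbance covariance the model would not be identified from
six binary indicators, and the association of interest is carried by the
path coefficient. A full Cholesky factor is available behind the
`full_covariance` spec flag for latent graphs without that conflict.

## Marginal likelihood and quadrature

The child-level likelihood is the r-dimensional integral of the conditional
Bernoulli likelihood against the standard-normal density of v. It is
approximated on a tensor-product Gauss–Hermite grid rescaled to the normal
weight (abscissas √2·a*, weights w*/√π, so weights sum to 1), with
log-sum-exp stabilization across nodes and per-element probability clamping
at 10⁻¹².

Adaptive quadrature recentres the grid per child at the posterior mode μ_v of
v and rescales by the Cholesky factor C of the curvature τ_v (the negative
inverse Hessian of log φ(v) + log f(y|v) at the mode). The weight correction
follows from the change of variables v = μ_v + C a:

    w*_k = w_k · det(C) · φ_r(α_k) / φ_r(a_k),   α_k = μ_v + C a_k.

The mode is found by a safeguarded Newton iteration (≤50 steps, gradient
tolerance 10⁻⁸, vectorized across children, step-halving). All three link
log-likelihoods are concave in the linear predictor (the logistic, normal and
Gumbel densities are log-concave), so the posterior objective is strictly
concave and the mode unique; the curvature I + J′WJ is positive definite by
construction, and any numerically non-PD case falls back to the unadapted
rule for that child.

Numerical behaviour to be aware of: at q = 7 the mode–curvature adaptive rule
agrees with a dense non-adaptive rule to roughly 10⁻⁵–10⁻⁶ per observation
when the latent disturbance SD is near 1, improving by orders of magnitude
for smaller SDs and with q (the implementation matches lme4's nAGQ
likelihood to 10⁻¹⁰ on an equivalent random-intercept model). Consistency
tests therefore run on a moderate-signal toy (disturbance SD 0.6) where both
rules are converged well below the asserted tolerances; the monotone
stabilization of |LL(q) − LL(q+2)| is asserted separately on the same data.

## Estimation

Maximum likelihood by L-BFGS-B with **exact analytic gradients** of the
frozen-grid objective. Because the adaptive nodes and weight corrections
depend on θ, estimation alternates:

1. freeze the per-child grid at the current θ;
2. run L-BFGS-B (bounded: coefficients ±25, log-SDs ±4; ftol 10⁻¹³,
   projected-gradient tolerance 5·10⁻⁶, memory 25) for at most
   `inner_maxiter` (default 60) iterations;
3. re-adapt the grid and evaluate the re-adapted log-likelihood.

The re-adapted LL is the merit function. Small decreases (up to
max(0.5, 10⁻⁴·|LL|)) are expected on the way to the adaptive fixed point,
because the quadrature error moves with θ; a larger drop means the optimizer
exploited a stale grid at small q, and the round is retried from the previous
iterate with a shorter leash. Convergence is declared when the inner run
terminates on its own and the re-adapted LL changes by less than 10⁻⁸
relative across a round. This outer/inner scheme replaces naive
finite-difference gradients of the fully adaptive objective: the frozen-grid
gradient is exact, two orders of magnitude cheaper, and the fixed point is
the same.

Starting values: per-indicator binary GLMs (statsmodels) give intercepts and
direct effects, free loadings start at 1, latent regressions and the
structural path at 0, L at the identity; a separation-prone starting
regression falls back to link(prevalence) with zero slopes and a warning.

Standard errors come from the inverse of the numerically differentiated
observed information — central differences of the analytic gradient at the
optimum (step 10⁻⁵·(1+|θ|)), with the adaptive grid frozen at θ̂. Parameters
fixed by identification get no SE and zero rows in the stored covariance, so
delta-method propagation downstream treats them as known constants. Wald
95% intervals are estimate ± 1.96·SE; odds-ratio intervals exponentiate the
endpoints; significance stars follow the two-sided Wald convention
(** p<0.001, * p<0.05).

Missing indicator values: listwise deletion by default (`missing="drop"`);
`missing="use"` keeps partially observed children and drops only the missing
terms from the conditional likelihood. Covariate missingness always drops
the row.

## Link comparison

`compare_links` fits the identical model under logit, probit and cloglog and
reports LL/AIC/BIC rows in that fixed order, selecting the AIC minimum with
ties resolved toward logit. Two caveats the experiments made visible: at
very small q the quadrature bias differs across links by more than a typical
AIC gap, so comparisons at q=3 are only trustworthy when the latent SD is
moderate; and with binary indicators the conditional link is only weakly
identified through the latent part — the information that separates logit
from probit comes from strong additive covariate effects spanning wide
probability ranges. The packaged `link_selection_preset` is built that way
(four ±2.0 direct binary effects, disturbance SD 0.5).

## Effect decomposition

With β₁ the morbidity ← malnutrition path, β₂ a covariate's path into
malnutrition and β₃ its path into morbidity, the package reports, on the
log-odds scale, direct = β₃, indirect = β₁β₂ and total = β₃ + β₁β₂, and their
exponentials as adjusted odds ratios, so AOR_total = AOR_direct·AOR_indirect
holds exactly before rounding. A covariate without a path into the mediator
has indirect exactly 0. This is the product-of-coefficients rule, not a
counterfactual mediation estimand. Confidence intervals use the delta method
on the estimated parameter covariance by default —
Var(β₁β₂) = β₂²V₁₁ + β₁²V₂₂ + 2β₁β₂V₁₂ — which is first-order: it matches
Monte-Carlo propagation closely when coefficient SEs are small relative to
the coefficients, and understates the spread otherwise. A seeded
nonparametric bootstrap (default B=200, percentile intervals, computed when
at least 80% of refits succeed) is available behind a flag.

## Synthetic data

`simulate_children` draws covariates from configurable categorical marginals,
latent disturbances through L, latents by the structural equations, and
indicators as Bernoulli through the chosen link — exactly the process the
likelihood integrates over, which is the point: the simulate → fit loop is
closed and testable. What it deliberately does **not** emulate: survey
design (clusters, strata, weights), spatially or serially correlated
covariates, informative missingness (only MCAR is supported), or measurement
error in covariates. Passing recovery tests therefore demonstrate that the
estimator inverts its own data-generating process at realistic signal
strengths, not that the model is correct for any particular survey.

The `paper_like_params` preset uses published adjusted-odds-ratio magnitudes
as true log-odds coefficients (structural path log 1.14; covariate effects
from roughly log 0.57 to log 1.26; child-age effects on stunting up to
log 5.58), free loadings 0.8–1.2, unit disturbance SDs, and intercepts
calibrated once by large-n simulation so indicator prevalences sit at
survey-like levels (stunting 38%, wasting 10%, underweight 24%, diarrhea
12%, cough 16%, fever 14%). Default covariate marginals mimic the survey's
category mix (three wealth levels, three education levels, and so on).

## Problem sizes and defaults

- q = 7 points per dimension with adaptation is the model default.
- The recovery harness (`run_recovery`) defaults to q = 5 adaptive at
  n = 3000 with 10 replicates: at the preset's signal strength the q=5
  adaptive LL sits within ~10⁻⁴ per observation of the converged value,
  which is far below sampling noise at n = 3000, and it keeps a 59-parameter
  10-replicate experiment to a few minutes.
- The link-recovery experiment runs q = 3 adaptive at n = 4000 with an inner
  iteration budget of 400; its preset has disturbance SD 0.5, where q=3
  adaptation is adequate and the AIC gaps (≈10–600) dwarf residual
  optimization slack.
- Degenerate inputs: a latent with all loadings fixed at 0 is estimable (the
  latent decouples; its variance parameter simply has zero gradient), and is
  reported by `validate_spec` as an anchoring violation; `fit` proceeds on
  identification warnings but raises on structural errors (cycles, unknown
  names, bad levels).

## Known limitations

- Tensor-product quadrature limits the latent dimension in practice (r ≤ 4).
- AIC/BIC comparisons inherit quadrature bias at small q; compare links at
  the same q and prefer q ≥ 5 when the estimated disturbance SDs approach 1.
- The delta-method CI for products is first-order (see above).
- The observed information is differenced at the frozen-grid objective;
  the neglected dependence of the adaptive grid on θ is of the same order as
  the quadrature error itself.
- No survey-design corrections; estimates are child-level conditional ML.
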