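# mimicgsem

Generalized structural equation (MIMIC) models for the joint analysis of
child malnutrition and morbidity from binary survey indicators.

Child malnutrition and morbidity are not directly observable as single
variables: anthropometric deficits (stunting, wasting, underweight) and
recent illness (diarrhea, cough, fever) are noisy binary manifestations of
two underlying traits, and the traits themselves are causally linked —
undernourished children get sick more. Analyzing the six indicators with six
separate regressions ignores both facts. This package fits the combined
model: two latent endogenous variables measured by three Bernoulli
indicators each, with measured covariates as causes, a structural
malnutrition → morbidity path, and direct child-level effects on the
indicators. It is aimed at biostatisticians and epidemiologists who want
latent-trait regression with mediation-style effect decomposition on
child-health survey data, or a fully simulated testbed for that workflow.

## The model

For child *i* with covariate vector *x*:

    η₁ = b₁′x + ζ₁                      (malnutrition)
    η₂ = b₂′x + β·η₁ + ζ₂               (morbidity)
    P(y_j = 1 | η, x) = g⁻¹(α_j + λ_j·η_parent(j) + γ_j′·x_direct)

with ζ ~ N(0, Σ_v), anchor loadings fixed at 1 (stunting, diarrhea) for
identification, and g ∈ {logit, probit, cloglog}. The marginal likelihood
integrates the latent vector out by adaptive Gauss–Hermite quadrature
(per-child posterior mode μ_v and curvature τ_v, Cholesky-rescaled nodes)
and is maximized with exact analytic gradients. Link families are compared
by AIC/BIC. Covariate effects on morbidity decompose as

    direct = β₃,   indirect = β₁·β₂,   total = β₃ + β₁·β₂

on the log-odds scale (β₁: morbidity ← malnutrition, β₂: malnutrition ←
covariate, β₃: morbidity ← covariate), reported as adjusted odds ratios, so
AOR_total = AOR_direct × AOR_indirect exactly. See `docs/methods.md` for
assumptions, numerics and limitations.

## Worked example

Simulate a survey-like dataset under the built-in study model (published
effect magnitudes, realistic prevalences), fit it, and decompose the
breastfeeding effect:

```python
import mimicgsem as mg
from mimicgsem.effects import decompose, effect_ci

spec = mg.default_paper_spec()                      # the 2-latent study model
cfg = mg.SimulationConfig(n=2000, seed=7, true_params=mg.paper_like_params(spec))
data = mg.simulate_children(cfg, spec)

fit = mg.fit(spec, data, link="logit", q=5, adaptive=True)
mg.standard_errors(fit)
print(f"loglik = {fit.loglik:.2f}, AIC = {fit.aic:.2f}, BIC = {fit.bic:.2f}")

est = effect_ci(fit, decompose(fit, ("breastfeeding", "yes")), method="delta")
lo, hi = est.aor_ci("total")
print(f"direct AOR {est.aor_direct:.2f}, indirect AOR {est.aor_indirect:.2f}, "
      f"total AOR {est.aor_total:.2f} (95% CI {lo:.2f}-{hi:.2f})")
```

Output from this exact run:

```
loglik = -5179.10, AIC = 10476.20, BIC = 10806.65
direct AOR 0.80, indirect AOR 1.00, total AOR 0.80 (95% CI 0.68-0.93)
```

Reading it: breastfed children have 0.80 times the adjusted odds of the
morbidity trait, essentially all of it a direct effect — at n=2000 the
mediated path (β₁·β₂, true value log 1.14 × log 0.90 ≈ −0.014) is too small
to show. The fitted maternal-BMI → malnutrition AOR in the same run is 0.74
(flagged **), against a generating value of 0.71. `fit.wald_table()` gives
the full Table-3-style report; `mg.render_effect_tables(fit)` formats the
direct and indirect/total AOR tables with 95% CIs and significance stars.

The same pipeline is scriptable from the shell:

```bash
mimicgsem simulate --n 2000 --seed 7 --out data.csv
mimicgsem fit --data data.csv --link logit --q 5 --out fit.json
mimicgsem effects --fit fit.json --out effects.csv
mimicgsem compare-links --data data.csv --out links.csv
mimicgsem recover --n 3000 --reps 10 --seed 0 --out recovery.csv
```

Every command writes a `<out>.manifest.json` with options, seed, package
version and input checksums.

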