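# twinliab

Liability-threshold twin analysis of censored age-at-onset binary traits.

`twinliab` is built for the classical twin design applied to registry data:
a late-onset disease endpoint (the motivating case is total hip arthroplasty
for primary hip osteoarthritis) observed in a population twin register that
is linked to a procedure register over a finite calendar window, so that
most individuals are right-censored, some die before they can become cases,
and events before the window start are invisible. It is aimed at genetic
epidemiologists who want to go from two delimited registry files (or a
simulated stand-in) to concordance tables, tetrachoric correlations,
ACE-family variance components with censoring weights, competing-risk
cumulative incidence, and age-resolved heritability curves.

## The model

Each twin carries a latent liability L ~ N(0, 1). The trait "affected by
age t" is L > τ(t) for a strictly decreasing threshold τ, so the cumulative
onset probability is K(t) = 1 − Φ(τ(t)). Within a pair the liabilities are
bivariate normal with correlation structured by zygosity:

    r_MZ = a² + d² + c²          r_DZ = a²/2 + d²/4 + c²

where a², d², c², e² are the additive genetic, non-additive genetic, shared
environment, and unique environment proportions of liability variance
(a² + d² + c² + e² = 1); broad-sense heritability is H² = a² + d².
Estimation works on the probit scale: the saturated model frees one
correlation per zygosity group, the ACE / ADE / AE / CE submodels constrain
the correlations as above, and all are fitted by maximising the sum over
pairs of the log bivariate-probit likelihood. Nested models are compared by
likelihood-ratio test, non-nested ones by AIC.

Censoring and death are handled on the age scale. Cumulative incidence with
death as a competing state uses the Aalen–Johansen estimator with delayed
entry. For the liability models, "affected by horizon t" responses are
weighted by inverse probability of censoring: death before t is a fully
observed non-case (an outcome state), while administrative window end and
emigration are censoring. Because twins share a birth date, the pair-level
weight uses the shared censoring time, 1/G(max(u₁, u₂)⁻); and because the
administrative censoring age is a known covariate, the analysis at horizon
t is restricted to individuals whose potential censoring age reaches t,
with a Kaplan–Meier G for the genuinely random censoring inside that group.

A fully-tested synthetic twin-register generator reproduces the study
conditions (zygosity mix, 6% lifetime liability-scale prevalence with onset
rising sharply after age 50, sex-specific Gompertz mortality, ~88% right
censoring) so the whole pipeline is exercised end-to-end without any data
access.

## Worked example

```python
from twinliab import (PairContingency, tetrachoric, concordance_rates,
                      model_casewise, default_params, simulate_cohort,
                      censoring_weights, make_pair_table, fit_components)

# published complete-pair counts for monozygotic male pairs:
# 10 both affected, 57 discordant, 4558 neither
tab = PairContingency(10, 57, 4558, stratum="MZM")
print(concordance_rates(tab)["probandwise"])   # 0.260
est = tetrachoric(tab)
print(est.rho_, est.ci95_)                     # 0.704 (0.543, 0.815)
print(model_casewise(0.80, 0.06))              # 0.512

# simulate a registry-scale cohort under known components and refit
params = default_params(n_pairs=45_000, seed=1, emit_prevalent=True)
cohort = simulate_cohort(params)
w = censoring_weights(cohort, horizon_age=70.0)
fit = fit_components(make_pair_table(cohort, weighted_outcomes=w), "ACE")
print(fit.components_)
# {'a2': 0.474, 'd2': 0.0, 'c2': 0.211, 'e2': 0.316}
```

The first block reproduces a published concordance table row: given 10
concordant and 57 discordant monozygotic male pairs, the probability that a
co-twin of an affected man is affected is 0.26, and the liability-scale
within-pair correlation is 0.70. The `model_casewise` value is the
case-wise concordance implied by the liability model at correlation 0.80
and prevalence 6%. The second block generates 45,000 twin pairs under the
truth (a², c², e²) = (0.47, 0.21, 0.32) with competing mortality and heavy
administrative censoring, then recovers those components with the weighted
ACE fit — here (0.474, 0.211, 0.316), with a 95% CI for a² of (0.13, 0.82)
reflecting how little information a rare trait carries even at this scale.

A command-line umbrella is included:

```
twinliab simulate --n-pairs 45000 --seed 1 --out registry/
twinliab build-cohort --twins registry/twin_register.csv \
    --events registry/arthroplasty_register.csv --out cohort.csv --ledger ledger.json
twinliab concordance --cohort cohort.csv
twinliab fit --cohort cohort.csv --model ACE --horizon 70
twinliab cif --cohort cohort.csv --by-sex
twinliab run --out-dir full_run --seed 1     # end-to-end pipeline + plots
```

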