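# Methods

## The liability-threshold twin model

A binary age-at-onset trait is modelled through a latent standard-normal
liability L per individual; "affected by age t" means L > τ(t), with τ
strictly decreasing so that cumulative onset K(t) = 1 − Φ(τ(t)) accumulates
with age. Twin pairs share liability according to the classical twin
decomposition: monozygotic (MZ) pairs correlate at r_MZ = a² + d² + c²,
dizygotic (DZ, same-sex or opposite-sex) pairs at r_DZ = a²/2 + d²/4 + c²,
where a² (additive genetic), d² (non-additive genetic), c² (shared
environment) and e² (unique environment) partition the unit liability
variance. ACDE is rejected as unidentifiable with twin pairs alone: MZ and
DZ correlations give two equations, and D and C push them in opposite
directions.

Assumptions inherited from the classical twin design: equal environments
across zygosity, no assortative mating or gene–environment interaction for
the constrained models, and equal trait prevalence in MZ and DZ twins. The
last is testable and is property-tested on simulator output.

## Tetrachoric correlation

An exchangeable pair table (n_cc both affected, n_cd discordant, n_dd
neither) is fitted by maximising the double-entered symmetric
bivariate-normal likelihood with a single threshold common to both members;
the discordant mass is split evenly across the two off-diagonal cells. With
two free parameters against two degrees of freedom the ML solution
reproduces the observed prevalence and concordant-affected share, so the
estimate is also the solution of the moment equations. Orthant
probabilities are evaluated through Owen's T (machine precision; the
quadrature route in `scipy.stats.multivariate_normal` is reserved for
cross-checks so the two never share code). Confidence intervals are
delta-method on the atanh scale, which keeps them inside (−1, 1) and always
containing the estimate. Tables with a zero margin return a boundary flag
rather than ±1; an optional +0.5 continuity correction (off by default) is
available for zero cells.

Case-wise concordance has two deliberately distinct senses: count-based
proband-wise/pairwise rates (2 n_cc/(2 n_cc + n_cd) and n_cc/(n_cc + n_cd))
computed from tables, and the model-based case-wise concordance
Φ₂⁺(z, z; ρ)/q at threshold z = Φ⁻¹(1 − q), used wherever a (ρ, q) pair is
reported without counts.

## Variance-component fitting

All models maximise the (optionally weighted) sum over pairs of the log
bivariate-probit likelihood, aggregated over the at most ~30 distinct
(zygosity, sexes, outcomes) cells, which makes each fit essentially
instantaneous at any cohort size. Thresholds are sex-specific in the
sex-adjusted mode (opposite-sex pairs contribute a mixed-threshold term)
and zygosity-specific in the sex-stratified mode, which drops opposite-sex
pairs because they have no single sex. The saturated model frees one
correlation per zygosity group (same-sex and opposite-sex DZ separately by
default; `pool_dz=True` shares them). Components are parameterised by
stick-breaking on the unit simplex (logistic transforms), correlations by
atanh; optimisation is L-BFGS-B with up to five jittered restarts, and a
fit is declared converged when the optimiser succeeds or the gradient norm
falls below 10⁻⁴ (the likelihood scale grows with the summed weights, so an
absolute 10⁻⁸ gradient criterion is not meaningful for weighted fits).
Confidence intervals are delta-method from the finite-difference observed
information on the transformed scale, truncated to the parameter range;
boundary estimates therefore show as 0.00 with a one-sided interval. For
weighted fits the information is model-based, not a sandwich — intervals
there are descriptive rather than exactly calibrated, a known limitation.

Heritability is a² + d² with its delta CI for component models; for the
saturated model the moment-based 2(r_MZ − r_DZ) is reported and labelled as
such, with DZ correlations pooled by pair count when freed separately.
Nested models are compared by the plain likelihood-ratio chi-square (no
chi-bar-square boundary mixture — matching the usual reporting convention
for these tables); non-nested by AIC = 2k − 2LL with k counted exactly as
parameterised, so the identity is reproducible from the outputs.

## Competing risks and censoring weights

The cohort is an illness–death system on the age scale: healthy → case
(arthroplasty) and healthy → dead, with administrative window end and
emigration the only censoring. Cause-specific cumulative incidence is the
Aalen–Johansen estimator with delayed entry at the age at window start;
pointwise variances use the standard delta-method (Marubini–Valsecchi)
estimator, verified against `lifelines` and a hand-computed fixture.

For the liability models, the response at horizon t is "case by t", where
death before t without a case event is a fully observed non-case — death is
an outcome state, not censoring. Weights are inverse probability of
censoring, with two design choices that matter and were validated by
simulation:

- **Pair weights use the shared censoring time.** Twins share a birth date
  and therefore an administrative censoring age, so the probability that a
  pair is fully observed is G(max(u₁, u₂)), not G(u₁)G(u₂). Since G is
  monotone this is simply max of the member weights. The independent
  product rule remains available (`weight_policy="product"`) but is
  inconsistent under shared censoring and measurably attenuates both twin
  correlations.
- **Administrative censoring is handled by positivity restriction.** The
  potential administrative censoring age is a known covariate
  (`admin_censor_age`). Weighting by a marginal censoring distribution
  mixes in individuals who could never be observed at the horizon and, when
  mortality makes the outcome entry-dependent, biases the estimand. The
  analysis at horizon t therefore uses the subcohort whose potential
  censoring age reaches t; within it, the genuinely random censoring
  (emigration) is reweighted through a delayed-entry Kaplan–Meier G. The
  classic marginal-KM weighting (`g_method="km"`) is kept for data whose
  censoring ages are random, unknown in advance, and outcome-independent.

Weights are capped (default 20, with the capped count logged) against 1/G
tail instability; under the administrative scheme the cap rarely binds
because within-subcohort weights stay near one.

## The synthetic twin register

The generator emulates a nationwide register linkage. Per pair: zygosity
from the mix (21.6% MZ / 37.6% same-sex DZ / 40.8% opposite-sex DZ of
individuals, matching the motivating cohort's composition), pair sex from
the observed per-zygosity male shares, a birth year from 1900–1975 with
sampling weights growing at 3%/year (a register dominated by younger
cohorts; the range itself is an arbitrary but documented default), and a
bivariate normal liability at the zygosity's correlation. Onset age is the
deterministic monotone transform of liability through τ⁻¹, with
K(t) = p∞ Φ((t − 70)/12) scaled so lifetime prevalence at age 100 is 6% —
onset is negligible before 50 and concentrated between 60 and 85. Death is
sex-specific Gompertz (b·e^{0.095 t}, b = 4.3×10⁻⁵ men / 2.6×10⁻⁵ women);
emigration is exponential at 0.001/year. Pairs are retained only if both
members are alive at the window start (rejection sampling, the
left-truncation of a 1995-style register), and exits are the first of
onset, death, administrative end (15.67 years after the start) or
emigration, ties resolving case > death > censored. With these defaults
~0.8% of individuals are observed cases, ~11% die in-window and ~88% are
censored, inside the published 84–91% range.

Onsets before the window start are silently emitted as non-cases by
default — the registry cannot see them — with `emit_prevalent=True`
revealing them for experiments that need the estimand free of that bias.
An optional age-dependent loading schedule turns the liability into an
age-indexed factor process (A/D/C/E factors with the twin correlation
structure, renormalised to unit variance at each age) for testing whether
age-resolved fits detect changing architecture; with constant loadings it
reduces to the closed form.

What the generator does not emulate: zygosity misclassification, diagnostic
miscoding, birth-cohort effects on onset or mortality (age and calendar
time are exchangeable here), within-pair dependence of death, or
non-ignorable emigration. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated sampling structure, not
robustness to those real-data features.

## Age-resolved curves

"Affected by age t" defines a landmark family of traits. At each grid age
(default 40–90 by 5 years) the cohort is reweighted at horizon t and the
proband-wise concordance per zygosity class (weighted p₁₁/q), the marginal
incidence, and optionally the full ACE/AE fit are recomputed from scratch —
thresholds included. Concordance CIs are percentile intervals from a
weighted bootstrap over pairs (B = 200 by default; weights are treated as
fixed across resamples); component CIs are delta-method. Grid ages with no
affected pairs, too few affected pairs (default minimum 5), or a
non-converged fit are flagged undefined rather than plotted. Curves are
pointwise; no smoothing. The marginal curve and the Aalen–Johansen case CIF
are two estimators of the same quantity when observation starts at birth,
and are property-tested against each other in that configuration.

## The component-recovery experiment

The central validation regenerates 25 cohorts of 45,000 pairs under the
default truth (a², c², e²) = (0.47, 0.21, 0.32) with competing mortality
and ~85–88% administrative censoring, fits the sex-adjusted IPCW ACE model
to each, and compares the mean components to the truth. Design choices:

- `emit_prevalent=True`: the estimator targets "affected by t"; with
  pre-window onsets silenced that estimand is unidentifiable for old
  entrants, so the registry-silencing bias (a deliberate feature of the
  default generator) is switched off for estimator validation.
- Horizon 70 years: inside the positivity subcohort the window in which
  death can suppress an onset is at most one study-window length, keeping
  the estimand-level attenuation of all three components below one
  percentage point (measured on a 100-replicate characterisation run with
  a seed range disjoint from the test seeds), while K(70) = 3% still yields
  enough affected pairs.
- 25 replicates: each replicate carries roughly the information of the
  motivating study (a² standard error ≈ 0.15), so the mean over 25 has a
  Monte-Carlo SE near 3 percentage points on a² — the recovery check is a
  bias check at that resolution, not a precision claim.

## Problem sizes and numerics

The test suite simulates cohorts between 500 and 50,000 pairs (the
registry-scale fixtures use 45,000, the study size), bootstraps with
20–150 replicates, and runs the 25-replicate recovery and age-trend
experiments at full scale; the whole suite completes in well under a
minute on one core because fits aggregate to cells. Orthant probabilities
are clipped at 10⁻³⁰⁰ before logs; correlations are clamped away from ±1 at
10⁻¹²; ages are exact day differences divided by 365.25. Determinism: one
`numpy` Generator per simulation seed, and the pipeline stamps every output
with the seed and a hash of the scientific configuration, so reruns are
byte-identical.

## Known limitations

Weighted-fit confidence intervals ignore the weight-estimation and
within-pair-weight dependence (no sandwich). The tetrachoric of a published
count table can differ from a model-based published correlation when the
latter was computed on the underlying full data — two strata of the
motivating study's concordance table show exactly that residual
discrepancy, which count-based recomputation cannot close. The age-varying
loading model is the minimal extension that makes age-resolved recovery
testable; it is not a substantive model of changing genetic architecture.
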