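# Methods

This note documents the model, its assumptions, the synthetic study
conditions, and the design choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Demographic model

Incidence `h[a, t]` is the probability that a girl of exact age `a`
(0–14) is cut in calendar year `t`. Prevalence at child ages is the
cohort-lagged sum `P[a, t] = Σ_{i≤a} h[i, t−(a−i)]`; for ages 15–49
prevalence is carried forward along cohorts, `P[a, t] = P[a−1, t−1]` —
no cutting after age 14, no reversal. Ages are integer single years and
years are calendar years, exactly as the displayed recursion.

Boundary conditions: the lagged sum needs incidence up to 14 years
before the projection start. `stationary_incidence` reconstructs an
age-specific hazard from a baseline child prevalence profile under
stationarity (first differences); `trended_incidence` extends a base
hazard across all years, including pre-horizon years, with a geometric
trend `(1 − trend)^(t − 2020)` — i.e. the historic trajectory is assumed
to have followed the same proportional decline before the base year.

The age pattern of cutting within 0–14 is not identified by the inputs
the pipeline consumes, so it is a generator parameter. The default
(`DEFAULT_AGE_PATTERN`) concentrates ~61% of cutting before age 5 and
tapers to near zero by 14, a shape consistent with survey evidence that
most cutting happens in early childhood. Scenario results in relative
terms (impact fractions, dominance orderings) are insensitive to this
choice; absolute case counts scale with it.

Populations are held constant by age over the horizon (no fertility or
mortality dynamics); the female share of each age group is 0.5. Both are
deliberate simplifications — the harness studies program arithmetic, not
population projections.

## The social-norms regression

`norms.fit` estimates, by maximum likelihood (statsmodels), the logistic
model

```
logit P(daughter cut) = β0 + β1·support_i + β2·support̄_c + γ·controls
```

where `support_i` is the mother's own support for FGM and `support̄_c`
the simple mean of support in her community (including herself; a
leave-one-out variant is available). Controls: age linear, wealth
quintile and education ordinal-as-numeric, urban binary, religion
one-hot against the largest category. Frequency weights are honoured
when a weight column is named. Perfect separation raises a dedicated
error advising the L1-regularized fallback rather than returning
divergent estimates.

The generator simulates daughter-cut outcomes from the *empirical*
community mean of the sampled support indicators — the same regressor
the fit uses — so the fitted model is correctly specified on synthetic
data and confidence intervals attain nominal coverage. This is what the
parameter-recovery suite checks (95% CIs cover each generating
coefficient in ≥90% of 50 replicates at n = 50,000).

## Impact chain

Steps, applied per country:

1. fit the regression on baseline microdata;
2. flip supporter attitudes at the cell's effect size — 0.710 direct,
   0.446 indirect; non-supporters never change and changes never revert;
3. recompute community support from the shifted individual values;
4. evaluate the model per woman and average within each exposure cell
   (eligible × {direct, indirect, none}); interventions exist only in
   eligible communities (baseline support strictly > 0.5; ties at
   exactly 0.5 are ineligible);
5. mix cells into a national probability: among eligible communities the
   direct cell gets weight equal to direct coverage `c`, the indirect
   cell `min(1 − c, r·c)` with `r` the realized indirect ratio, the
   unreached cell the remainder; non-eligible communities contribute
   their baseline probability. The impact fraction is `(p0 − p1)/p0`.

**Expectation vs sampling mode.** The default "expectation" mode
replaces each supporter's indicator with the fractional expected support
`1 − effect` before recomputing community means and predicting. For any
linear statistic (support mass, community means) this equals the mean of
the "sampling" mode (independent Bernoulli flips) exactly — the tested
invariant. Because the logistic is nonlinear, the *cell probability*
under expectation mode is a smoothed version of the sampling mean and
can differ from it by several percent relative; the deterministic
expectation mode is nevertheless the default because it makes scenario
results bit-for-bit reproducible without seed management, and both modes
move monotonically with the effect size.

**From probability to incidence.** The national probability reduction
maps to incidence multiplicatively: scenario incidence equals
counterfactual incidence × (1 − IF(t)), where IF(t) is the impact
fraction computed at year *t*'s coverage along the linear ramp — the
phase-in follows the coverage trajectory. After 2030 the impact persists
at its final level times a persistence factor (default 1.0; 0.5 and 0
are sensitivity options). The functional mapping from a probability
reduction to age-specific incidence is a documented modelling choice; a
uniform multiplicative scaling across ages 0–14 is the simplest option
consistent with a norms-level mechanism.

**Counterfactual.** Only the historic trend operates: incidence declines
at `(1 − trend)` per year from its base-year level. Cell probabilities
are computed once at baseline; the coverage ramp, not re-evolved
attitudes, drives the phase-in. Cases averted are counterfactual minus
scenario cases, accumulated 2020–2030 and 2031–2050 ("an additional
generation of girls" is read as the printed 2031–2050 window).

**Spillover.** The diffusion cell — indirect-strength attitude change in
communities already below 50% support — is off by default (the primary
assumption is no impact where views are already negative) and enabled by
the `spillover_all_communities` sensitivity row, phased in with combined
coverage.

## Costing

Eight interventions (community empowerment, mass/social media, provider
prevention training, legislation development, mobile courts, legal
capacity building, psychosocial support, provider care training), each
with a target population (communities = total population / 600, health
providers, legal personnel, the country itself, or women at first
birth) and a PIN rule: share of communities above 50% approval
(shrinking over time as approval declines at the historic trend), 100%
for countries without legislation and zero otherwise, 100% for legal
capacity, or the FGM type-3 share for psychosocial support.

Coverage rules: community empowerment is costed at the **direct**
coverage ramp (indirect reach costs nothing); media, courts, trainings
and care at the **combined** ramp; legislation is a fixed per-country
item front-loaded evenly over the first two years and identical across
scenarios. The ramp is linear from 0 at the start year to the target at
2030 — the standard costing-tool convention — and a pandemic delay
shifts the ramp start while keeping the 2030 end, lowering achieved
coverage in every year.

The planning ratio (3 indirect communities per direct community) fixes
the direct coverage target — combined target / (1 + 3), so 25% direct
for the high scenario — and is deliberately separate from the *realized*
indirect ratio in `EffectSizes`: assuming fewer communities are actually
sensitized changes impact but not the budget, reproducing the
cost/impact separation of the sensitivity table.

Markups over service delivery: program HR 1%, supervision 2%, transport
2%, communications 1%, M&E 7.5%, management 12%, safety 1% in conflict
countries — component sums 25.5% and 26.5%. (A published total for this
schedule is quoted as "26.5–27.5%", which does not match its own
components; the package exposes the component sums and documents the
discrepancy rather than forcing agreement.)

Unit-cost transfer multiplies a reference cost by the ratio of
per-capita GDP (PPP). The shipped reference table
(`default_unit_costs`) is synthetic: order-of-magnitude 2020-USD values
(e.g. $2,500 per community for a multi-year empowerment program, $60 per
psychosocial contact) at a reference GDP of $5,000, intended to be
replaced by real program cost data via the CSV reader. Absolute cost
totals on synthetic inputs therefore have no external meaning; ratios,
shares and orderings do.

All outputs are constant 2020 USD with no inflation or discounting.
Provider and legal-personnel counts are inputs (the synthetic generator
uses 1.5 and 0.2 per 1,000 persons); they may be fractional expected
counts, which keeps costs exactly homogeneous of degree one in
population.

## Synthetic study conditions

A synthetic country assigns each survey community a component of the
approval mixture — default 55% of communities at mean support 0.85, 25%
at 0.45, 20% at 0.12, i.e. a high-burden setting where just over half of
communities are majority-approving — and draws individual support as
Bernoulli at the community mean (a covariate-linked logit shift is
optional; the default keeps covariates independent of support, since no
joint distribution is identified). Daughter-cut outcomes come from
`default_cut_coefficients` (individual support +1.5, community support
+2.0 on the logit scale, mild protective wealth/education/urban
gradients). Communities average 600 persons; the survey take per cluster
is configurable. Multi-country sets vary population (1–50 million), GDP
PPP ($1,500–12,000), mixtures, historic trends (0–6%/year), legislation
status (~74% have laws, matching 8 of 31 countries lacking them),
type-3 share, and regions; every fourth country is flagged as a conflict
setting and roughly 9 in 31 as data-poor.

What the generator does **not** emulate: DHS sampling weights,
stratification, nonresponse, spatial correlation between neighbouring
communities, measurement error in reported attitudes, or any real
country's parameters. Passing tests therefore demonstrate that the
pipeline's arithmetic, statistics and orderings are correct under the
assumed data-generating process — not that any published country total
is reproduced, which would require the original surveys and unpublished
unit costs.

## Problem sizes

Defaults chosen for the routine suite: parameter recovery uses 50
replicates of 100 communities × 500 women (n = 50,000); scenario and
sensitivity tests use 6 countries of 30 × 60; the full synthetic run
uses 31 countries of 40 communities × 100 women (124,000 women), which
completes in seconds while keeping per-country fits well conditioned.

## Known limitations

- The expectation-mode cell probability smooths over flip randomness
  (see above); sampling mode with many seeds is the reference when the
  distinction matters.
- Cell probabilities are computed at baseline attitudes; the approval
  trend shrinks the costed PIN pool over time but does not re-evolve the
  regression inputs, so impact fractions are anchored at base-year
  norms. Under a zero-trend sensitivity this is exact; under strong
  trends it slightly overstates late-decade impact.
- A zero historic trend raises the counterfactual and hence both costs
  *and* cases averted here; treating that row as cost-only (as a
  published sensitivity table does) would require an absolute rather
  than relative impact mapping.
- Constant unit costs (no economies of scale), constant populations, and
  a single national regression per country (no subnational pooling
  choices) are all scope decisions, not oversights.
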