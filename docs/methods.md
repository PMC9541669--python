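# Methods

## The population process

`mooseipm` models moose abundance in J management units over T years with a
discrete-time stochastic Gompertz process on the log scale, with harvest
subtracted on the natural scale. Writing `mu[j,t]` for the log of
postharvest abundance in the winter of year `t` (December of `t-1` through
February of `t`), the expected postharvest abundance one year later is

    N[j,t+1] = exp( mu[j,t] + r_max + b[j] mu[j,t]
                    + beta_pred[j] c[j,t] + beta_cN[j] c[j,t] mu[j,t]
                    + beta_deer[j] d[j,t] ) - E[j,t]

where `c` and `d` are standardized canid and deer sighting rates from the
fall hunt of year `t`, `E[j,t]` is that fall's harvest, and

    beta_pred[j] = beta_canids[j] + beta_bears * BearDensity[j]

composes a predator coefficient from the unit's canid effect and its static
(standardized) black-bear density. `r_max` is the intrinsic growth rate
from minimal abundance (N = 1) and is shared across units; `b[j]` is the
unit's density-dependence coefficient. Unit-level coefficients
(`b`, `beta_canids`, `beta_cN`, `beta_deer`, plus the detection parameters
below) arise from normal population-level distributions with hyper-means
and between-unit SDs.

Timeline convention: the breeding population observed in winter `t`
produces the spring recruitment of year `t`; those moose are harvested in
fall `t`; the survivors are the winter `t+1` population. Hunter counts in
fall `t` therefore observe the *realized preharvest* population
`exp(mu[j,t+1]) + E[j,t]`. Because the fall data of the final study year
reference one more winter, the latent state vector carries T+1 winters
(the terminal one unobserved).

The canid-by-abundance interaction multiplies the *log* abundance
(`beta_cN * c * mu`), not the natural-scale abundance: only the log-N form
keeps the model inside the linearized Gompertz family, where the
interaction acts as a covariate-dependent shift of the density-dependence
coefficient (`b_eff = b + beta_cN * c`). This is an explicit override point
(`log_growth_increment`) for users who want a different functional form.

## Observation layers

**Aerial surveys.** A winter survey provides an estimate `N_hat` and SE
`se`. The latent state in a surveyed winter follows
`Normal(log N_hat, (se/N_hat)^2)` — the SE mapped to the log scale by the
first-order delta method — and *no process error is applied in surveyed
winters*; in unsurveyed winters the state follows the Gompertz prediction
with process SD `sigma_proj`. Surveys are treated as fixed data; the
survey estimator itself is not modelled.

**Hunter questionnaires.** Moose counted by hunters in unit `j`, fall `t`
follow

    y ~ Poisson(lambda),
    log lambda = alpha[j] + theta_days[j] z_days + theta_snow[j] z_snow
                 + log(exp(mu[j,t+1]) + E[j,t]) + eta[j,t],
    eta ~ Normal(0, sigma_obs^2)

with the realized preharvest population as offset. `alpha[j]` is the log of
the average observable proportion of preharvest moose; days hunted and the
fall snow index enter as standardized covariates (not as an exposure
offset, matching the linear-predictor form of the source model); `eta` is
an observation-level random effect absorbing overdispersion, sampled (not
marginalized) within MCMC.

**Harvest.** Hunters hold class-specific tags (bull/cow/calf); a fraction
return questionnaires. Total harvest is

    E = sum_k Eo_k + Binomial(n_k, s_k)

with `Eo_k` the reported harvest, `n_k` tags minus respondents, `s_k` the
respondents' success rate. Inside the fit the binomial sum is replaced by
its matching normal (its mean `n s` is large) and the continuous `E[j,t]`
is sampled as a latent variable bounded by `[sum Eo, sum Eo + sum n]`; a
`harvest_mode="fixed"` option pins `E` at its expectation. When a class has
zero respondents in a unit-year, its success rate falls back to the unit's
pooled multi-year success.

## Priors

- `r_max ~ Normal(0.304, 0.08)` — informative, from published estimates of
  moose intrinsic growth.
- Density dependence: hyper-mean of `b` has a Normal(0, 10) prior truncated
  at [-2, 2]; unit-level `b[j]` are bounded to the same interval. The
  truncation is applied as hard bounds without renormalizing in the
  hyper-parameters (the bounds are >100 between-unit SDs away in practice).
- Hyper-means of all other coefficients: Normal(0, 10). Between-unit SDs,
  `sigma_proj`, `sigma_obs`: half-Normal(0, 5). These "vague" scales are
  package defaults, declared in `PriorConfig` and overridable.
- Initial abundance: per unit, `mu[j,0] ~ Normal(log N_hat, se_log)` from
  the unit's first-winter survey; if the first winter is unsurveyed, the
  earliest survey supplies the mean with an SD floor of 0.5.

Units with fewer than 2 aerial surveys are excluded at model assembly with
a logged warning; their dynamics cannot be anchored.

## Sampler

The posterior is sampled by adaptive Metropolis-within-Gibbs, the same
family of scheme the original JAGS analysis used, vectorized in numpy:

- latent states `mu`: single-site Gaussian random-walk updates on an
  even/odd-year schedule (each site's full conditional involves only its
  neighbours), with per-site adaptive step sizes;
- block moves that fix the slow directions of state-space posteriors, all
  per unit and all *eta-compensated* — the overdispersion field moves with
  the path so every Poisson rate is exactly invariant and acceptance is
  decided by the process terms, the survey anchors and the eta prior
  (large counts would otherwise pin the path to a few percent per
  proposal): a *level* move (shift the whole path, counter-shift the
  detection intercept), a *segment* move (shift one maximal run of
  unsurveyed states between anchors), a *trend* move (tilt a run linearly
  or by a random Brownian-bridge shape, covering interior bulges of long
  gaps), and a *tilt* move (shift the effort coefficient, tilt the
  unanchored path along the effort covariate);
- *swap* moves trading each observation coefficient against the eta field
  (`p += delta, eta -= delta * z` leaves the rates exactly invariant), the
  fast operator for the detection/overdispersion tradeoff;
- a per-unit and a population-level *canid-ridge* move trading the canid
  effect against the canid-by-abundance interaction, which the data
  identify only through the combination `beta_canids + mu * beta_cN`;
- harvest latents `E` and overdispersion `eta`: vectorized independent
  random-walk updates;
- unit-level coefficients: vectorized per-unit random-walk updates;
- hyper-means: conjugate Gibbs draws (truncated-normal for the
  density-dependence mean);
- `r_max`, `beta_bears`, all scale parameters: univariate slice sampling
  (scales in log space);
- one joint "ridge" move shifting `r_max` and all density-dependence terms
  along the growth/density-dependence tradeoff, which is weakly identified
  and otherwise mixes slowly.

Step sizes adapt by Robbins–Monro toward 44% acceptance during burn-in
only, so the post-burn-in chain is a fixed Markov kernel. Initial values:
latent states at interpolated log survey estimates (lifted if the implied
postharvest would be non-positive), observation parameters at per-unit
least-squares fits of `log(count/offset)` on the observation covariates —
a zero start strands chains in an inflated-variance region — and variance
parameters at the corresponding residual spreads.

Default `FitConfig`: 3 chains, 16,000 adaptive burn-in sweeps, 40,000
sampling sweeps thinned to every 20th (2,000 kept per chain), six to eight
minutes for 15 units x 20 years on one CPU. These desk-scale settings
replace the published three-chain two-million-iteration JAGS run; the long
settings remain reachable through the config. Convergence is gated on the
split Gelman–Rubin diagnostic (all parameters and stored latents < 1.1).

## Synthetic data

The generator mirrors the full generative chain and is the package's study
design for recovery experiments. Defaults emulate the Ontario moose
monitoring program: 55 units (recovery experiments use 15) x 20 years;
per-unit survey counts on {2..7} with median 5, the first winter always
surveyed (it anchors the initial-abundance prior); survey error lognormal
with CV 0.2 (SE reported as CV x estimate); questionnaire response
averaging 74.1% (annual range about 0.51-0.80); per-unit target harvest
rates uniform on [0.035, 0.113] of preharvest abundance; initial unit
sizes log-uniform between about 200 and 5,400 moose (provincial total
around 90,000). Population-level generative parameters default to the
published posterior means (r_max 0.487, mean b -0.058, mean canid effect
-0.195, canid x log-abundance 0.023, deer -0.022, bears -0.013, detection
intercept -0.445, effort effect 0.734, snow effect 0.028). Between-unit
SDs and the process/observation SDs are not published at that level; the
defaults (e.g. sigma_proj 0.08, sigma_obs 0.15, sigma_b 0.015) are chosen
once as values typical of northern-ungulate monitoring and declared in
`TrueParams`. Initial unit sizes are log-uniform between the published
low and high reference unit abundances (100 and 6,000 moose in an
average-sized unit); the low end matters for identifiability, since the
canid effect and its abundance interaction separate only where log
abundance varies, and growth near 100 moose is what informs r_max beyond
its prior.

Two deliberate realism choices:

- *Tag feedback.* Tag allocations track the current expected preharvest
  population, holding each unit's harvest proportion near its target, as
  Ontario reduced tags while populations declined. With static tags a
  declining unit's harvest rate compounds and the unit crashes to the
  degenerate floor, which the monitoring record contradicts.
- *Model/generator asymmetry.* The generator applies process noise in
  every transition and draws surveys as lognormal measurements of the true
  state; the fitted model (following the source analysis) replaces the
  process density by the survey density in surveyed winters. The fit is
  thus an approximation of the generative truth, exactly as it is for real
  data.

What the generator does **not** emulate: spatial survey mechanics
(stratified random block design), nonresponse bias correlated with hunting
success, Indigenous harvest, poaching, winter-tick mortality, and temporal
variation in bear density. Passing recovery tests therefore show the
estimator is consistent under the model's own assumptions plus these
simplifications — not that those assumptions hold for any real dataset.

Snow-index construction for real data (weekly station depths summed over
October-December, ordinary kriging onto a 10 km grid, polygon averaging)
is implemented in `covariates`; the kriging defaults (exponential
variogram, zero nugget, WLS fit to the binned empirical semivariogram,
pair-count weights) are declared choices, since the original interpolation
settings are unreported. The generator draws unit-level snow indices
directly from a smooth unit + year + noise decomposition rather than
simulating stations.

## Analyses

- **Growth rates.** Per draw,
  `lambda = (P_2017 + P_2018) / (P_1999 + P_2000)` on realized preharvest
  abundances, summarized with quantile 95% intervals; a unit is flagged
  changed when the interval excludes 1. The total-period ratio is primary;
  an annualized form `lambda^(1/18)` is optional.
- **Elasticities.** Under proportional harvest `E = h * preharvest` the
  equilibrium is closed-form:
  `mu* = -(r_max + beta_pred c + beta_deer d + log(1-h)) / (b + beta_cN c)`,
  stable iff the denominator is negative. Elasticities perturb each
  population-level parameter by delta in {1%, 5%, 10%} per posterior draw
  and divide the relative equilibrium change by delta; harvest levels are
  the mean and the 2.5th/97.5th percentiles of the unit-year posterior-mean
  harvest proportions; covariates sit at their (standardized) mean of
  zero. Draws without a stable equilibrium after perturbation are excluded
  and counted, never silently dropped. The package reproduces the
  *procedure* and the sign/ordering structure of the published elasticity
  table; the printed magnitudes depend on the original dataset's covariate
  means and posterior and are not reproduction targets.
- **Harvest counterfactuals.** Per draw, a deterministic Gompertz
  projection from the posterior-median initial log abundance of an average
  unit runs under a baseline per-year harvest-proportion schedule and a
  modified schedule (per-year multipliers, e.g. a 35% reduction over the
  first eight years); bands are quantiles across draws, and the
  final/initial abundance ratio summarizes stability.

## Numerical notes and limitations

- Degenerate growth (harvest >= production) yields -inf process density in
  the fit; simulation floors abundance at 1 moose and flags the unit-year.
- Survey SEs of zero are floored at 1e-3 on the log scale.
- The binomial-to-normal harvest approximation is poor when `n s` is small
  (a few tags); such unit-years carry negligible harvest, so the effect on
  abundance is immaterial.
- `split_rhat` uses the classic split-chain between/within variance ratio,
  not the rank-normalized variant.
- Identifiability of `r_max` against density dependence relies on the
  informative prior and on between-unit contrast in abundance; in designs
  where all units sit near their equilibria the posterior of `r_max` leans
  on its prior.
- The elasticity base point, harvest levels, and covariate means are
  explicit arguments, so any alternative base point is reproducible.
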