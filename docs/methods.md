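# Methods

## The model

`dynocc` fits a multi-species, multi-season (dynamic community) occupancy
model to repeated point-count detection histories collected in two primary
periods (years), each containing K short secondary count intervals assumed
demographically closed.

For species *i*, site *j*, year *t* and interval *k*:

- Latent occupancy: `z(j,t,i) ~ Bernoulli(ψ_{j,t,i})`, with
  `logit ψ_{j,1,i} = u_i` in the first year and, in the second,
  `ψ_{j,2,i} = z(j,1,i)·φ_i + (1 − z(j,1,i))·γ_i` — occupied sites persist
  with probability φ, empty sites are colonized with probability γ. The
  second-year equation is a probability-scale mixture, the standard dynamic
  form; with U(0,1) priors on φ and γ no link function is involved.
- Observation: `y(j,t,k,i) ~ Bernoulli(p_{j,t,k,i} · z(j,t,i))` with
  `logit p = v_{i,t} + β_date,i·date + β_time,i·time + β_prevDet,i·prevdet`.
  The detection intercept is year-specific because the change in
  detectability between years is itself a quantity of interest.
- Occupancy, persistence and colonization vary only by species and year
  (no site covariates, no spatial autocorrelation, no data augmentation for
  never-observed species).

Hierarchy: `u_i ~ N(μ_u, σ_u²)`, `v_{i,t} ~ N(μ_{v,t}, σ_{v,t}²)`,
`logit φ_i ~ N(μ_φ, σ_φ²)`, `logit γ_i ~ N(μ_γ, σ_γ²)`. Community
hyper-means carry flat U(0,1) priors on the probability scale (equivalently
a standard-logistic density on the logit scale); hyper-SDs carry U(0,5)
priors, a conventional weakly-informative choice for logit-scale spreads.
Detection coefficients β get independent N(0, variance 100) priors with no
community pooling. A non-hierarchical mode (`PriorConfig(hierarchical=False)`)
replaces the species-level normals with independent flat-U(0,1)-equivalent
priors; it exists for small single-species validation problems where the
posterior can be computed by quadrature.

### Covariates

`date` is day-of-season, `time` minutes since midnight, both z-scored over
surveyed visits only (constants retained for back-transform); after
standardization the choice of origin is immaterial. `prevdet(j,t,k,i)` is 1
exactly when species *i* was recorded in the immediately preceding interval
of the same visit (0 for the first interval). "Previous interval" rather
than "any earlier interval" is the reading adopted throughout, and the
simulator builds the covariate the same way, sequentially within each visit.

### Missingness

Site-years without survey records are masked, not zero-filled, and
contribute no detection-likelihood terms (missing at random). Latent states
are still defined and sampled at unsurveyed site-years — they are needed to
propagate the year-1 → year-2 dynamics — but occupied-site counts sum only
over the sites surveyed in each year.

## Sampler

A native Metropolis-within-Gibbs scheme:

- `z`: exact Gibbs draws from the closed-form full conditional. Year-1
  states condition on the year-2 state through the φ/γ transition; a single
  detection forces `z = 1`.
- `u`, `v`, β, and (hierarchical) `logit φ`, `logit γ`: component-wise
  adaptive random-walk Metropolis. The species dimension factorizes, so all
  species are proposed and accepted/rejected simultaneously as vectors.
- Non-hierarchical φ, γ: conjugate Beta draws given the latent transition
  counts.
- Hyper-parameters: scalar random-walk Metropolis.

Proposal scales adapt every 50 sweeps toward a 0.44 acceptance rate (the
scalar-target optimum) with a diminishing Robbins-Monro step, during
burn-in only; the post-burn-in chain is strictly Markovian. One global seed
spawns independent per-chain PCG64 streams (`numpy.random.SeedSequence`),
so runs are bit-reproducible. Initial states are overdispersed: `z` starts
at 1 wherever detected and Bernoulli(0.5) elsewhere; intercepts at the
logit of naive frequencies clamped to [0.05, 0.95]; coefficients at zero.

Bookkeeping: each chain retains `floor((chain_length − burn_in)/thin)`
draws; the field-standard protocol of 3 chains × 160,000 sweeps with
10,000 burn-in and thinning by 10 retains 15,000 per chain. Retained draws
include all parameters, the latent states (optional) and the per-draw
occupied-site sums. Percentiles everywhere use linear interpolation
(`numpy.percentile` default), pinned so summaries are bit-stable.

## Derived quantities

- Detectability change: `Δp_i = invlogit(v_{i,2}) − invlogit(v_{i,1})` per
  draw, evaluated at the covariate reference point (standardized date and
  time 0, no previous detection). Marginalizing over observed covariates is
  a defensible alternative; the centered reference is the default because
  it requires no weighting convention.
- Occupied sites: the sum of the latent Z matrix over surveyed sites per
  year per draw; the change is the year-2 sum minus the year-1 sum.
- Rate of change: `λ = [ψ₂/(1−ψ₂)]/[ψ₁/(1−ψ₁)]`, computed per draw from
  finite-sample occupancy (fraction of surveyed sites occupied in that
  draw) so that λ and the site change are mutually consistent; a
  parametric-ψ variant is available (`lambda_draws(..., parametric=True)`).
  Draws where finite-sample ψ hits 0 or 1 have undefined odds and are
  excluded, with the exclusion count reported per species.
- Significance: a quantity is flagged significant when its 2.5–97.5
  percentile interval excludes the reference (0 for differences, 1 for λ).
- Occupancy–detectability correlation: Pearson r across species of
  posterior-mean p vs posterior-mean ψ, with a Fisher-z confidence
  interval; at least 4 species are required (the Fisher interval needs
  n > 3).

## Diagnostics

- Gelman–Rubin: the split-chain variant (each chain halved before the
  between/within comparison), which also detects within-chain drift;
  formula in `diagnostics.py`. The alarm threshold is 1.1. All-constant
  chains return 1 by convention with a warning. Single-chain runs are
  diagnosed by splitting the chain into halves.
- Effective sample size: autocovariance via FFT, combined across split
  chains with the pooled-variance correction, truncated by the initial
  positive sequence (paired lags accumulated while their sum is positive),
  capped at the total draw count. A constant chain returns 0.
- Bayesian p-value: for each retained draw a replicate detection history is
  simulated from that draw's detection probabilities and latent states,
  conditioning on the observed covariates (including the observed
  previous-detection indicator, which keeps the expected totals identical
  for observed and replicate data). The discrepancy is Freeman–Tukey on
  per-site-year-species detection totals, `Σ(√d − √E[d])²` — standard for
  occupancy models — with squared Pearson residuals available via
  `statistic="pearson"`. The p-value is the fraction of draws with
  `T_rep ≥ T_obs`, reported pooled and per species; because the pooled and
  across-species-mean aggregations can differ, both are exposed.

## Synthetic data

The generator emulates a two-winter forest point-count survey: 2 primary
periods, four 2.5-minute intervals per visit, and the unbalanced design of
186 both-year sites, 25 first-year-only and 16 second-year-only
(`study_mimic_design()`, giving 211/202 surveyed points per year, 227
total). Default hyper-parameters are a community mean occupancy of 0.4 and
mean per-interval detectability of 0.3 with logit-scale SDs of 1, moderate
persistence (0.7), low colonization (0.2), weak negative date and null time
effects, and a positive previous-detection effect (mean 0.5) — a regime a
diverse resident landbird community plausibly occupies. Dates are uniform
over a 90-day season and start times over a 5-hour morning window, constant
across the intervals of a visit.

What the generator does *not* emulate: spatial structure among sites,
observer effects, abundance-driven (N-mixture) detection heterogeneity,
distance classes, and any misfit between model and data. Passing recovery
and calibration tests therefore demonstrates correctness of the estimator
under the model's own assumptions, not robustness to their violation.

## Numerical choices

- All Bernoulli likelihood algebra is done on the log scale with softplus
  (`log(1+eˣ) = max(x,0) + log1p(e^{−|x|})`); inverse logit is branch-split
  for stability.
- The latent-state conditional returns 1 when both the all-miss probability
  and the unoccupied probability vanish (prior certainty wins).
- Zero-variance covariates raise rather than silently producing NaNs.
- Degenerate λ draws are excluded, never clipped.
- Ties in percentile computations are resolved by linear interpolation.

## Problem sizes used in validation

Recovery tests simulate 10-species × 100-site × 2-year communities and
refit with 3 chains × 5,000 sweeps (1,000 burn-in, thin 4) across 20
replicates, checking that 95% CRIs cover the true species-level ψ, φ and γ
at a rate in [85%, 100%]. The quadrature check uses 1 species × 3 sites ×
2 intervals against a 400×400 grid. Bayesian-p calibration uses ten
6-species × 30-site fits. These sizes give stable Monte-Carlo behaviour
while keeping the full suite quick to run; the sampler itself is routinely
run at the 227-site × 35-species scale.

## Known limitations

- The sampler supports one or two primary periods; longer series would
  need the z-update generalized to interior years.
- No within-chain parallelism; chains run sequentially.
- Detection coefficients are unpooled across species by design; with very
  sparse species this makes their posteriors prior-dominated.
- The retained-draw bookkeeping is the package's own
  (`floor((L−B)/thin)` per chain); published analyses with the same
  nominal settings may report different retained counts depending on their
  monitoring protocol.
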