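# dynocc

Dynamic multi-species occupancy modelling with imperfect detection.

`dynocc` is for ecologists and biostatisticians who survey a community of
species with repeated point counts in two primary periods (e.g. two
winters bracketing a disturbance) and want to separate *real* changes in
site occupancy from changes in how detectable each species is. Raw
detection counts confound the two: a species can be recorded at fewer
points simply because it became harder to hear, and the bias can even flip
the apparent direction of change.

## The model

For species *i*, site *j*, year *t* and count interval *k*:

```
z(j,t,i) ~ Bernoulli(ψ_{j,t,i})            latent presence
logit ψ_{j,1,i} = u_i                       first year
ψ_{j,2,i} = z(j,1,i)·φ_i + (1−z(j,1,i))·γ_i  persistence / colonization
y(j,t,k,i) ~ Bernoulli(p_{j,t,k,i} · z(j,t,i))   observation
logit p = v_{i,t} + β_date·date + β_time·time + β_prevDet·prevdet
```

Species-level parameters are drawn from community hyper-distributions
(normal on the logit scale, flat U(0,1) hyper-priors on the probability
scale, U(0,5) on the SDs); detection coefficients get vague N(0, 100)
priors. The posterior is simulated by a native Metropolis-within-Gibbs
sampler: exact Gibbs updates for the latent `z`, vectorized adaptive
random-walk Metropolis for everything else, multiple reproducible chains.

From the posterior the package derives, per species: the change in
detectability `Δp`, the change in the number of occupied sites (sums of
the latent Z matrix over surveyed sites), and the occupancy rate of change
`λ = [ψ₂/(1−ψ₂)]/[ψ₁/(1−ψ₁)]`, each with a 95% credible interval and a
significance call. Convergence is monitored with the split-chain
Gelman–Rubin statistic and effective sample size; model fit with a
posterior-predictive Bayesian p-value (Freeman–Tukey discrepancy).

A synthetic-community generator simulates detection histories from the
same model — including an unbalanced two-year design with one-year-only
site blocks — so every stage is testable end to end without field data.

## Worked example

```python
import dynocc

# simulate a 10-species community under the default regime
_, _, det, cov = dynocc.generate_community(seed=3)

cfg = dynocc.SamplerConfig(n_chains=2, chain_length=1500, burn_in=500, thin=2, seed=3)
samples = dynocc.sample_posterior(det, cov, dynocc.PriorConfig(), cfg)

table = dynocc.derived_summary_table(samples, det)
cols = ["species_code", "delta_p_mean", "lambda_mean", "delta_n_occ_mean",
        "delta_n_occ_lo", "delta_n_occ_hi", "delta_n_occ_significant"]
print(table[cols].round(3).head(5).to_string(index=False))
```

prints

```
species_code  delta_p_mean  lambda_mean  delta_n_occ_mean  delta_n_occ_lo  delta_n_occ_hi  delta_n_occ_significant
       sp000        -0.142        0.254           -21.659           -36.0          -2.975                     True
       sp001         0.401       12.865            21.426            15.0          25.000                     True
       sp002         0.199        1.349             3.593            -4.0          10.000                    False
       sp003        -0.136        1.937             7.349            -8.0          21.025                    False
       sp004        -0.010        2.602            10.458             0.0          21.000                    False
```

`sp000` lost detectability (Δp = −0.14) **and** occupied ground: its
occupancy odds in year 2 are about a quarter of year 1 (λ = 0.25) and it
disappeared from roughly 22 surveyed sites, with a credible interval
excluding zero. `sp002`–`sp004`'s intervals straddle no-change, so their
shifts are not distinguishable from sampling noise.

The `examples/` directory walks through each capability (simulation and
CSV ingestion, fitting, derived statistics, diagnostics, the one-command
pipeline); a thin CLI (`dynocc simulate|ingest|fit|diagnose|report|run-all`)
wraps the same pipeline for shell use.

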