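"""Fit the hierarchical dynamic occupancy model to a simulated community and
summarize the posterior.

Three Metropolis-within-Gibbs chains; latent presence states are updated by
exact Gibbs draws, everything else by adaptive random-walk Metropolis.
"""

import numpy as np

import dynocc

_, _, det, cov = dynocc.generate_community(seed=2)
cfg = dynocc.SamplerConfig(n_chains=3, chain_length=2000, burn_in=500, thin=3, seed=2)
samples = dynocc.sample_posterior(det, cov, dynocc.PriorConfig(), cfg)

summary = dynocc.summarize_posterior(samples)
print(summary[summary["param"].str.startswith(("phi", "gamma"))].round(3).to_string(index=False))
# Each row is one species' persistence (phi) or colonization (gamma)
# probability: posterior mean, SD and the 2.5/97.5 percentile credible
# interval, pooled over the three chains after burn-in and thinning.

psi1 = dynocc.inv_logit(samples.pooled("u")).mean(axis=0)
print("\nposterior mean year-1 occupancy by species:", np.round(psi1, 3))
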