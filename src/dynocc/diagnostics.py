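"""Convergence and goodness-of-fit diagnostics.

Split-chain Gelman-Rubin potential scale reduction factor, autocorrelation
effective sample size with initial-positive-sequence truncation, and a
posterior-predictive Bayesian p-value with a Freeman-Tukey discrepancy on
per-site-year-species detection totals.

Formulas (pinned):

  Split each of M chains of length N into halves -> m = 2M sequences of
  length n.  W = mean of within-sequence variances; B/n = variance of
  sequence means; var+ = (n-1)/n * W + B/n; rhat = sqrt(var+ / W).

  ESS: rho_t = 1 - (W - mean_m c_{t,m}) / var+, with c_{t,m} the lag-t
  autocovariance of sequence m; sum paired lags (rho_{2k} + rho_{2k+1})
  while the pair sum stays positive; ESS = m*n / (1 + 2 * sum rho).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DetectionArray, SurveyCovariates
from .model import inv_logit
from .sampler import PosteriorSamples

__all__ = [
    "gelman_rubin",
    "effective_sample_size",
    "bayesian_pvalue",
    "DiagnosticsReport",
    "diagnostics_report",
]


def _split_chains(chains: np.ndarray) -> np.ndarray:
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be a 2-D (n_chains, n_draws) array")
    M, N = chains.shape
    if M < 2 or N < 10:
        raise ValueError("need >= 2 chains of length >= 10")
    n = N // 2
    return chains[:, : 2 * n].reshape(2 * M, n)


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (values near 1 indicate
    convergence; > 1.1 is the usual alarm threshold).

    Chains that are all constant and equal return 1 by convention, with a
    warning, since the between/within ratio is then 0/0.
    """
    seq = _split_chains(chains)
    m, n = seq.shape
    W = seq.var(axis=1, ddof=1).mean()
    if W == 0.0:
        warnings.warn("zero within-chain variance; returning rhat = 1 by convention")
        return 1.0
    B_over_n = seq.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def _autocov(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance (divisor n) at all lags, via FFT."""
    n = x.size
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    return acov


def effective_sample_size(chains: np.ndarray) -> float:
    """Autocorrelation-time ESS over all (split) chains pooled.

    A constant chain carries no information about the posterior spread and
    returns 0 with a warning.
    """
    seq = _split_chains(chains)
    m, n = seq.shape
    W = seq.var(axis=1, ddof=1).mean()
    if W == 0.0:
        warnings.warn("constant chain; effective sample size is 0 by convention")
        return 0.0
    B_over_n = seq.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B_over_n
    acov = np.stack([_autocov(s) for s in seq])           # (m, n)
    rho = 1.0 - (W - acov.mean(axis=0)) / var_plus
    # initial positive sequence: accumulate paired lags while positive
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0.0:
            break
        tau += 2.0 * pair
        t += 2
    ess = m * n / tau
    return float(min(ess, m * n))


def _simulate_totals(p: np.ndarray, z: np.ndarray, surveyed: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """One replicate detection array's per-(site, year, species) totals."""
    J, T, K, S = p.shape
    occ = z[:, :, None, :] * surveyed[:, :, None, None]
    y_rep = (rng.random(p.shape) < p) * occ
    return y_rep.sum(axis=2)


def bayesian_pvalue(samples: PosteriorSamples, det: DetectionArray,
                    cov: SurveyCovariates, seed: int = 0,
                    max_draws: int = 500,
                    statistic: str = "freeman-tukey") -> tuple[float, np.ndarray]:
    """Posterior-predictive check: probability that replicated data are more
    extreme than the observed data under the fitted model.

    For each retained draw, a replicate detection history is simulated from
    that draw's detection probabilities and latent states (conditioning on
    the observed covariates, including the previous-detection indicator) and
    a discrepancy between detection totals and their expectations is
    computed for both observed and replicate data.  The p-value is the
    proportion of draws with T_rep >= T_obs; values near 0 or 1 flag lack of
    fit.  Freeman-Tukey is the default discrepancy; "pearson" (squared
    Pearson residuals) is the alternative.

    Returns (overall_p, per_species_p).
    """
    if samples.z_draws is None:
        raise ValueError("bayesian_pvalue requires stored latent states (store_z=True)")
    if statistic not in ("freeman-tukey", "pearson"):
        raise ValueError("statistic must be 'freeman-tukey' or 'pearson'")
    rng = np.random.default_rng(seed)
    n_total = samples.n_chains * samples.n_retained
    idx = (np.arange(n_total) if n_total <= max_draws
           else np.linspace(0, n_total - 1, max_draws).astype(int))

    y_tot = (det.y * det.surveyed[:, :, None, None]).sum(axis=2).astype(float)  # (J,T,S)
    surveyed = det.surveyed.astype(float)
    v = samples.pooled("v")
    bd = samples.pooled("beta_date")
    bt = samples.pooled("beta_time")
    bp = samples.pooled("beta_prevdet")
    zd = samples.z_draws.reshape(n_total, *samples.z_draws.shape[2:]).astype(float)

    J, T, K, S = det.y.shape
    T_obs = np.empty((len(idx), S))
    T_rep = np.empty((len(idx), S))
    for r, d in enumerate(idx):
        x = (v[d].T[None, :, None, :]
             + bd[d][None, None, None, :] * cov.date[:, :, :, None]
             + bt[d][None, None, None, :] * cov.time[:, :, :, None]
             + bp[d][None, None, None, :] * cov.prevdet)
        p = inv_logit(x)
        z = zd[d]
        expected = (p * surveyed[:, :, None, None]).sum(axis=2) * z      # (J,T,S)
        rep_tot = _simulate_totals(p, z, surveyed, rng)
        if statistic == "freeman-tukey":
            T_obs[r] = ((np.sqrt(y_tot) - np.sqrt(expected)) ** 2).sum(axis=(0, 1))
            T_rep[r] = ((np.sqrt(rep_tot) - np.sqrt(expected)) ** 2).sum(axis=(0, 1))
        else:
            var = (p * (1 - p) * surveyed[:, :, None, None]).sum(axis=2) * z
            var = np.maximum(var, 1e-12)
            T_obs[r] = (((y_tot - expected) ** 2) / var).sum(axis=(0, 1))
            T_rep[r] = (((rep_tot - expected) ** 2) / var).sum(axis=(0, 1))

    per_species = (T_rep >= T_obs).mean(axis=0)
    overall = float((T_rep.sum(axis=1) >= T_obs.sum(axis=1)).mean())
    return overall, per_species


@dataclass
class DiagnosticsReport:
    """rhat/ESS per monitored scalar plus goodness-of-fit summary."""

    table: pd.DataFrame                 # param, rhat, ess, flagged
    bayes_p: float
    bayes_p_per_species: np.ndarray
    rhat_threshold: float = 1.1
    notes: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return not self.table["flagged"].any()

    @property
    def mean_species_bayes_p(self) -> float:
        return float(np.mean(self.bayes_p_per_species))


def diagnostics_report(samples: PosteriorSamples, det: DetectionArray,
                       cov: SurveyCovariates, seed: int = 0,
                       rhat_threshold: float = 1.1,
                       families: tuple[str, ...] = ("u", "v", "phi", "gamma",
                                                    "beta_date", "beta_time",
                                                    "beta_prevdet"),
                       max_draws: int = 500) -> DiagnosticsReport:
    """Convergence table over species-level parameters plus the Bayesian
    p-value.  Parameters whose rhat exceeds the threshold are flagged."""
    rows = []
    for name in families:
        arr = samples.draws[name]                      # (C, N, ...)
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        shape = arr.shape[2:]
        for q in range(flat.shape[2]):
            ch = flat[:, :, q]
            if ch.shape[0] == 1:       # single chain: compare its two halves
                n = ch.shape[1] // 2
                ch = ch[0, : 2 * n].reshape(2, n)
            if np.allclose(ch.var(axis=1), 0):
                rhat, ess = 1.0, 0.0
            else:
                rhat = gelman_rubin(ch)
                ess = effective_sample_size(ch)
            label = name if not shape else f"{name}[{','.join(map(str, np.unravel_index(q, shape)))}]"
            rows.append({"param": label, "rhat": rhat, "ess": ess,
                         "flagged": rhat > rhat_threshold})
    table = pd.DataFrame(rows)
    overall, per_sp = bayesian_pvalue(samples, det, cov, seed=seed, max_draws=max_draws)
    return DiagnosticsReport(table=table, bayes_p=overall, bayes_p_per_species=per_sp,
                             rhat_threshold=rhat_threshold)
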