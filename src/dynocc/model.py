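"""The hierarchical dynamic community occupancy model.

Latent occupancy z(j, t, i) is Bernoulli: in the first primary period
logit psi = u_i; between periods occupied sites persist with probability
phi_i and empty sites are colonized with probability gamma_i, so
psi_2 = z_1 * phi_i + (1 - z_1) * gamma_i on the probability scale.
Detections given presence are Bernoulli with
logit p = v_{i,t} + b_date * date + b_time * time + b_prevdet * prevdet,
and y ~ Bern(p * z), the standard zero-inflated observation model.

Species-level intercepts and transition probabilities are drawn from
community hyper-distributions on the logit scale; community hyper-means
carry flat U(0,1) priors on the probability scale (standard-logistic on the
logit scale) and hyper-SDs carry U(0, 5) priors.  Detection coefficients get
independent vague Normal(0, variance 100) priors with no community pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DetectionArray, SurveyCovariates

__all__ = [
    "CommunityParams",
    "LatentOccupancy",
    "PriorConfig",
    "inv_logit",
    "logit",
    "occupancy_prob",
    "detection_prob",
    "detection_logits",
    "conditional_z_probability",
    "log_joint",
]


def inv_logit(x):
    """Numerically stable inverse logit."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def logit(p):
    p = np.asarray(p, dtype=float)
    out = np.log(p) - np.log1p(-p)
    return out if out.ndim else float(out)


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    """log(inv_logit(x)) = -softplus(-x), stable for large |x|."""
    return -np.logaddexp(0.0, -x)


@dataclass
class CommunityParams:
    """All species-level parameters plus the community hyper-parameters.

    Shapes: u (S,), v (S, T), betas (S,), phi/gamma (S,) on the probability
    scale.  ``hyper`` maps names (mu_u, sd_u, mu_v (T,), sd_v (T,), mu_phi,
    sd_phi, mu_gamma, sd_gamma) to values; hyper-SDs must be positive.
    """

    u: np.ndarray
    v: np.ndarray
    beta_date: np.ndarray
    beta_time: np.ndarray
    beta_prevdet: np.ndarray
    phi: np.ndarray
    gamma: np.ndarray
    hyper: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.u = np.atleast_1d(np.asarray(self.u, dtype=float))
        self.v = np.atleast_2d(np.asarray(self.v, dtype=float))
        for name in ("beta_date", "beta_time", "beta_prevdet", "phi", "gamma"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if np.any((self.phi < 0) | (self.phi > 1)) or np.any((self.gamma < 0) | (self.gamma > 1)):
            raise ValueError("phi and gamma must lie in [0, 1]")
        for k, val in self.hyper.items():
            if k.startswith("sd") and np.any(np.asarray(val) <= 0):
                raise ValueError(f"hyper SD {k} must be positive")

    @property
    def n_species(self) -> int:
        return self.u.shape[0]

    @property
    def n_years(self) -> int:
        return self.v.shape[1]


@dataclass
class LatentOccupancy:
    """Binary presence states z(site, year, species)."""

    z: np.ndarray  # (J, T, S) uint8

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.uint8)
        if not np.isin(self.z, (0, 1)).all():
            raise ValueError("z must be binary")


@dataclass
class PriorConfig:
    """Prior specification.

    hierarchical=True gives the community model described in the module
    docstring.  hierarchical=False removes pooling: each species intercept
    gets an independent standard-logistic prior (equivalently a flat U(0,1)
    prior on the probability scale) and phi/gamma get flat U(0,1) priors,
    which makes their full conditionals Beta.
    """

    hierarchical: bool = True
    sd_upper: float = 5.0          # U(0, sd_upper) hyper-prior on community SDs
    beta_sd: float = 10.0          # Normal(0, beta_sd^2) prior on detection coefficients

    def __post_init__(self) -> None:
        if self.sd_upper <= 0 or self.beta_sd <= 0:
            raise ValueError("prior scale bounds must be positive")


def occupancy_prob(params: CommunityParams, species: int, year: int,
                   z_prev: int | np.ndarray | None = None):
    """Occupancy probability psi for one species in one primary period.

    Year index 0 uses the logit intercept; later years require the previous
    occupancy state and mix persistence and colonization on the probability
    scale.
    """
    if year == 0:
        return inv_logit(params.u[species])
    if z_prev is None:
        raise ValueError("z_prev required for dynamic years")
    z_prev = np.asarray(z_prev, dtype=float)
    out = z_prev * params.phi[species] + (1.0 - z_prev) * params.gamma[species]
    return out if out.ndim else float(out)


def detection_logits(params: CommunityParams, cov: SurveyCovariates) -> np.ndarray:
    """Linear predictor of detection, shape (J, T, K, S)."""
    x = params.v.T[None, :, None, :] \
        + params.beta_date[None, None, None, :] * cov.date[:, :, :, None] \
        + params.beta_time[None, None, None, :] * cov.time[:, :, :, None] \
        + params.beta_prevdet[None, None, None, :] * cov.prevdet
    return x


def detection_prob(params: CommunityParams, cov: SurveyCovariates,
                   j: int, t: int, k: int, i: int) -> float:
    """Detection probability for a single (site, year, interval, species)."""
    x = (params.v[i, t]
         + params.beta_date[i] * cov.date[j, t, k]
         + params.beta_time[i] * cov.time[j, t, k]
         + params.beta_prevdet[i] * cov.prevdet[j, t, k, i])
    return float(inv_logit(x))


def conditional_z_probability(psi: float, p_vec: np.ndarray, y_vec: np.ndarray) -> float:
    """Posterior probability that z = 1 given a detection history.

    A single detection forces presence; an all-zero history shrinks the prior
    psi by the probability of missing the species on every interval:
    psi * prod(1 - p) / (psi * prod(1 - p) + 1 - psi).
    """
    p_vec = np.asarray(p_vec, dtype=float)
    y_vec = np.asarray(y_vec)
    if p_vec.shape != y_vec.shape:
        raise ValueError("p_vec and y_vec lengths differ")
    if np.any(y_vec == 1):
        return 1.0
    miss = float(np.prod(1.0 - p_vec))
    num = psi * miss
    denom = num + (1.0 - psi)
    if denom == 0.0:           # psi == 1 and all p == 1 with y all 0: prior certainty wins
        return 1.0
    return num / denom


def _logistic_logpdf(x: np.ndarray) -> np.ndarray:
    # density of logit(U) for U ~ U(0,1)
    return x - 2.0 * np.logaddexp(0.0, x)


def _normal_logpdf(x, mu, sd):
    return -0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def log_joint(params: CommunityParams, z: LatentOccupancy, det: DetectionArray,
              cov: SurveyCovariates, priors: PriorConfig) -> float:
    """Log joint density of (parameters, latent states, data).

    Sums occupancy Bernoulli terms over all sites, detection Bernoulli terms
    over surveyed site-years (zero-inflated: where z = 0 an observed
    detection is impossible and the result is -inf), species-level priors
    given the hyper-parameters, and the hyper-priors.
    """
    for name in ("u", "v", "beta_date", "beta_time", "beta_prevdet", "phi", "gamma"):
        if not np.all(np.isfinite(getattr(params, name))):
            raise ValueError(f"non-finite parameter values in {name}")

    y = det.y
    zz = z.z.astype(float)
    J, T, K, S = y.shape

    # impossible configuration: detection where z = 0
    if np.any((y == 1) & (z.z[:, :, None, :] == 0) & det.surveyed[:, :, None, None]):
        return -np.inf

    total = 0.0
    # occupancy terms, year 1
    psi1 = inv_logit(params.u)                       # (S,)
    z1 = zz[:, 0, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        occ1 = z1 * np.log(psi1) + (1 - z1) * np.log1p(-psi1)
    occ1 = np.where(np.isnan(occ1), -np.inf, occ1)
    total += float(occ1.sum())
    # dynamic years
    for t in range(1, T):
        zp = zz[:, t - 1, :]
        psi_t = zp * params.phi[None, :] + (1 - zp) * params.gamma[None, :]
        zt = zz[:, t, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            occ = zt * np.log(psi_t) + (1 - zt) * np.log1p(-psi_t)
        occ = np.where(np.isnan(occ), -np.inf, occ)
        total += float(occ.sum())

    # detection terms where z = 1 on surveyed site-years (z = 0 contributes
    # probability one to the all-zero history)
    x = detection_logits(params, cov)
    mask = det.surveyed[:, :, None, None] & (z.z[:, :, None, :] == 1)
    ll = y * x - np.logaddexp(0.0, x)
    total += float((ll * mask).sum())

    # species-level priors and hyper-priors
    h = params.hyper
    if priors.hierarchical:
        total += float(_normal_logpdf(params.u, h["mu_u"], h["sd_u"]).sum())
        mu_v = np.atleast_1d(h["mu_v"])
        sd_v = np.atleast_1d(h["sd_v"])
        total += float(_normal_logpdf(params.v, mu_v[None, :], sd_v[None, :]).sum())
        total += float(_normal_logpdf(logit(params.phi), h["mu_phi"], h["sd_phi"]).sum())
        total += float(_normal_logpdf(logit(params.gamma), h["mu_gamma"], h["sd_gamma"]).sum())
        for mu_key in ("mu_u", "mu_phi", "mu_gamma"):
            total += float(_logistic_logpdf(np.asarray(h[mu_key])).sum())
        total += float(_logistic_logpdf(mu_v).sum())
        for sd_key in ("sd_u", "sd_v", "sd_phi", "sd_gamma"):
            sd = np.atleast_1d(h[sd_key])
            if np.any((sd <= 0) | (sd > priors.sd_upper)):
                return -np.inf
            total += float(-np.log(priors.sd_upper) * sd.size)
    else:
        total += float(_logistic_logpdf(params.u).sum())
        total += float(_logistic_logpdf(params.v).sum())
        # phi, gamma ~ U(0,1): density 1 on the probability scale

    for b in (params.beta_date, params.beta_time, params.beta_prevdet):
        total += float(_normal_logpdf(b, 0.0, priors.beta_sd).sum())
    return total
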