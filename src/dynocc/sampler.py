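"""Native Metropolis-within-Gibbs sampler for the community occupancy model.

Latent occupancy states are updated by exact Gibbs draws from their
closed-form full conditionals; species intercepts, detection coefficients
and (in the hierarchical model) logit-scale persistence/colonization are
updated by component-wise adaptive random-walk Metropolis; in the
non-hierarchical model phi and gamma have conjugate Beta full conditionals
given the latent transition counts and are drawn directly.  Proposal scales
adapt toward a 0.44 acceptance rate during burn-in only, so the post-burn-in
chain is Markovian.  One global seed spawns independent per-chain streams.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DetectionArray, SurveyCovariates
from .model import CommunityParams, LatentOccupancy, PriorConfig, inv_logit, log_joint, logit

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "initial_state",
    "sample_posterior",
    "summarize_posterior",
    "save_samples",
    "load_samples",
]

_TARGET_ACCEPT = 0.44
_ADAPT_INTERVAL = 50


@dataclass
class SamplerConfig:
    """MCMC run settings.

    The study protocol this mirrors ran three chains of length 160,000 with
    10,000 burn-in/adaptation sweeps and thinning by 10; tests use far
    shorter chains.  ``update_betas=False`` fixes the detection coefficients
    at zero (for covariate-free fits).
    """

    n_chains: int = 3
    chain_length: int = 160_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    update_betas: bool = True
    store_z: bool = True
    initial_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be < chain_length")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_retained(self) -> int:
        return (self.chain_length - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Retained draws organized chain-major.

    ``draws`` maps parameter-family names to arrays of shape
    (n_chains, n_retained, ...); ``z_draws`` holds latent states as
    (n_chains, n_retained, J, T, S) uint8 (or None when not stored);
    ``meta`` records the config, seeds and final acceptance rates.
    """

    draws: dict[str, np.ndarray]
    z_draws: np.ndarray | None
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_retained(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws for one family with chains concatenated: (n_total, ...)."""
        arr = self.draws[name]
        return arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])


def initial_state(det: DetectionArray, cov: SurveyCovariates,
                  rng: np.random.Generator,
                  priors: PriorConfig | None = None) -> tuple[CommunityParams, LatentOccupancy]:
    """Overdispersed but likelihood-consistent starting point.

    z starts at 1 wherever the species was detected and Bernoulli(0.5)
    elsewhere; intercepts start at the logit of naive frequencies clamped to
    [0.05, 0.95]; coefficients start at zero.
    """
    J, T, K, S = det.y.shape
    any_det = det.y.any(axis=2)                      # (J, T, S)
    z = np.where(any_det, 1, rng.random((J, T, S)) < 0.5).astype(np.uint8)

    surveyed_any = det.surveyed.any(axis=1)
    naive_psi = any_det.any(axis=1)[surveyed_any].mean(axis=0)        # (S,)
    u = logit(np.clip(naive_psi, 0.05, 0.95))

    v = np.zeros((S, T))
    for t in range(T):
        m = det.surveyed[:, t]
        if m.any():
            naive_p = det.y[m, t].mean(axis=(0, 1))                   # (S,)
            v[:, t] = logit(np.clip(naive_p, 0.05, 0.95))

    if T >= 2:
        both = det.surveyed.all(axis=1)
        z1, z2 = any_det[both, 0, :], any_det[both, 1, :]
        n1 = z1.sum(axis=0)
        phi = np.where(n1 > 0, (z1 & z2).sum(axis=0) / np.maximum(n1, 1), 0.5)
        n0 = (~z1).sum(axis=0)
        gam = np.where(n0 > 0, (~z1 & z2).sum(axis=0) / np.maximum(n0, 1), 0.2)
        phi = np.clip(phi, 0.05, 0.95)
        gam = np.clip(gam, 0.05, 0.95)
    else:
        phi = np.full(S, 0.5)
        gam = np.full(S, 0.2)

    hyper = {
        "mu_u": float(np.mean(u)), "sd_u": 1.0,
        "mu_v": v.mean(axis=0), "sd_v": np.ones(T),
        "mu_phi": float(np.mean(logit(phi))), "sd_phi": 1.0,
        "mu_gamma": float(np.mean(logit(gam))), "sd_gamma": 1.0,
    }
    params = CommunityParams(u=u, v=v, beta_date=np.zeros(S), beta_time=np.zeros(S),
                             beta_prevdet=np.zeros(S), phi=phi, gamma=gam, hyper=hyper)
    return params, LatentOccupancy(z=z)


def _softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + exp(x)) = max(x, 0) + log1p(exp(-|x|)); faster than logaddexp
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def _logistic_logpdf(x):
    return x - 2.0 * np.logaddexp(0.0, x)


class _ChainState:
    """Mutable single-chain state with vectorized update kernels."""

    def __init__(self, det: DetectionArray, cov: SurveyCovariates,
                 priors: PriorConfig, config: SamplerConfig,
                 rng: np.random.Generator):
        self.det = det
        self.cov = cov
        self.priors = priors
        self.config = config
        self.rng = rng
        J, T, K, S = det.y.shape
        if T > 2:
            raise NotImplementedError("sampler supports one or two primary periods")
        self.J, self.T, self.K, self.S = J, T, K, S

        self.y = det.y.astype(np.float64)
        self.surv4 = det.surveyed[:, :, None, None].astype(np.float64)  # (J,T,1,1)
        self.any_det = det.y.any(axis=2)                                # (J,T,S)
        self.params, self.zlat = initial_state(det, cov, rng, priors)
        self.z = self.zlat.z.astype(np.float64)

        p = self.params
        self.scales = {
            "u": np.full(S, config.initial_scale),
            "v": np.full((S, T), config.initial_scale),
            "bd": np.full(S, config.initial_scale),
            "bt": np.full(S, config.initial_scale),
            "bp": np.full(S, config.initial_scale),
            "lphi": np.full(S, config.initial_scale),
            "lgam": np.full(S, config.initial_scale),
            "mu_u": 0.3, "sd_u": 0.3, "mu_v": np.full(T, 0.3), "sd_v": np.full(T, 0.3),
            "mu_phi": 0.3, "sd_phi": 0.3, "mu_gamma": 0.3, "sd_gamma": 0.3,
        }
        self.acc = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in self.scales.items()}
        self.acc_total = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in self.scales.items()}
        self.n_updates = 0
        self.lphi = logit(p.phi)
        self.lgam = logit(p.gamma)
        self._refresh_x()

    # -- linear predictor ---------------------------------------------------
    def _refresh_x(self) -> None:
        p, cov = self.params, self.cov
        self.x = (p.v.T[None, :, None, :]
                  + p.beta_date[None, None, None, :] * cov.date[:, :, :, None]
                  + p.beta_time[None, None, None, :] * cov.time[:, :, :, None]
                  + p.beta_prevdet[None, None, None, :] * cov.prevdet)
        self.sp_x = _softplus(self.x)   # cached log(1 + e^x); kept in sync with x

    def _det_mask(self) -> np.ndarray:
        # detection terms count only where surveyed and occupied
        return self.surv4 * self.z[:, :, None, :]

    # -- latent states ------------------------------------------------------
    def update_z(self) -> None:
        p = self.params
        with np.errstate(divide="ignore"):
            lq = -self.sp_x * self.surv4                   # log(1-p), 0 where unsurveyed
            q = lq.sum(axis=2)                             # (J,T,S)
            lpsi1 = np.log(inv_logit(p.u))
            l1mpsi1 = np.log(inv_logit(-p.u))
            lphi1, lphi0 = np.log(p.phi), np.log1p(-p.phi)
            lgam1, lgam0 = np.log(p.gamma), np.log1p(-p.gamma)

            if self.T == 2:
                z2 = self.z[:, 1, :]
                a = lpsi1[None, :] + q[:, 0, :] + z2 * lphi1[None, :] + (1 - z2) * lphi0[None, :]
                b = l1mpsi1[None, :] + z2 * lgam1[None, :] + (1 - z2) * lgam0[None, :]
            else:
                a = lpsi1[None, :] + q[:, 0, :]
                b = np.broadcast_to(l1mpsi1[None, :], a.shape)
            prob1 = inv_logit(a - b)
            draw = self.rng.random((self.J, self.S))
            self.z[:, 0, :] = np.where(self.any_det[:, 0, :], 1.0, (draw < prob1).astype(float))

            if self.T == 2:
                z1 = self.z[:, 0, :]
                psi2 = z1 * p.phi[None, :] + (1 - z1) * p.gamma[None, :]
                a = np.log(psi2) + q[:, 1, :]
                b = np.log1p(-psi2)
                prob2 = inv_logit(a - b)
                draw = self.rng.random((self.J, self.S))
                self.z[:, 1, :] = np.where(self.any_det[:, 1, :], 1.0, (draw < prob2).astype(float))

    # -- component-wise Metropolis helpers ---------------------------------
    def _mh_accept(self, key: str, delta: np.ndarray) -> np.ndarray:
        logu = np.log(self.rng.random(np.shape(delta)) + 1e-300)
        acc = logu < delta
        self.acc[key] = self.acc[key] + acc
        self.acc_total[key] = self.acc_total[key] + acc
        return acc

    def update_u(self) -> None:
        p, S = self.params, self.S
        n1 = self.z[:, 0, :].sum(axis=0)
        n = float(self.J)

        def loglik(u):
            return -n1 * _softplus(-u) - (n - n1) * _softplus(u)

        prop = p.u + self.scales["u"] * self.rng.standard_normal(S)
        if self.priors.hierarchical:
            h = p.hyper
            lp_cur = -0.5 * ((p.u - h["mu_u"]) / h["sd_u"]) ** 2
            lp_new = -0.5 * ((prop - h["mu_u"]) / h["sd_u"]) ** 2
        else:
            lp_cur = _logistic_logpdf(p.u)
            lp_new = _logistic_logpdf(prop)
        delta = loglik(prop) + lp_new - loglik(p.u) - lp_cur
        acc = self._mh_accept("u", delta)
        p.u = np.where(acc, prop, p.u)

    def update_phi_gamma(self) -> None:
        if self.T < 2:
            return
        p = self.params
        z1, z2 = self.z[:, 0, :], self.z[:, 1, :]
        n11 = (z1 * z2).sum(axis=0)
        n10 = (z1 * (1 - z2)).sum(axis=0)
        n01 = ((1 - z1) * z2).sum(axis=0)
        n00 = ((1 - z1) * (1 - z2)).sum(axis=0)

        if not self.priors.hierarchical:
            p.phi = self.rng.beta(1.0 + n11, 1.0 + n10)
            p.gamma = self.rng.beta(1.0 + n01, 1.0 + n00)
            self.lphi = logit(p.phi)
            self.lgam = logit(p.gamma)
            return

        h = p.hyper
        for key, lcur, nA, nB, mu, sd in (
            ("lphi", self.lphi, n11, n10, h["mu_phi"], h["sd_phi"]),
            ("lgam", self.lgam, n01, n00, h["mu_gamma"], h["sd_gamma"]),
        ):
            prop = lcur + self.scales[key] * self.rng.standard_normal(self.S)

            def ll(x):
                return -nA * _softplus(-x) - nB * _softplus(x)

            delta = (ll(prop) - 0.5 * ((prop - mu) / sd) ** 2
                     - ll(lcur) + 0.5 * ((lcur - mu) / sd) ** 2)
            acc = self._mh_accept(key, delta)
            new = np.where(acc, prop, lcur)
            if key == "lphi":
                self.lphi = new
                p.phi = inv_logit(new)
            else:
                self.lgam = new
                p.gamma = inv_logit(new)

    def update_v(self) -> None:
        p = self.params
        m = self._det_mask()                                  # (J,T,1,S)
        dv = self.scales["v"] * self.rng.standard_normal((self.S, self.T))
        dv_b = dv.T[None, :, None, :]
        x2 = self.x + dv_b
        sp2 = _softplus(x2)
        dll = (m * (self.y * dv_b - sp2 + self.sp_x)).sum(axis=(0, 2))  # (T,S)
        if self.priors.hierarchical:
            h = p.hyper
            mu_v = np.atleast_1d(h["mu_v"])[:, None]          # (T,1)
            sd_v = np.atleast_1d(h["sd_v"])[:, None]
            cur = p.v.T
            new = cur + dv.T
            dlp = -0.5 * ((new - mu_v) / sd_v) ** 2 + 0.5 * ((cur - mu_v) / sd_v) ** 2
        else:
            dlp = _logistic_logpdf(p.v.T + dv.T) - _logistic_logpdf(p.v.T)
        acc = self._mh_accept("v", (dll + dlp).T)             # (S,T)
        p.v = p.v + dv * acc
        acc_b = acc.T[None, :, None, :]
        self.x = np.where(acc_b, x2, self.x)
        self.sp_x = np.where(acc_b, sp2, self.sp_x)

    def _update_beta(self, key: str, attr: str, c: np.ndarray) -> None:
        p = self.params
        m = self._det_mask()
        cur = getattr(p, attr)
        db = self.scales[key] * self.rng.standard_normal(self.S)
        dx = db[None, None, None, :] * c
        x2 = self.x + dx
        sp2 = _softplus(x2)
        dll = (m * (self.y * dx - sp2 + self.sp_x)).sum(axis=(0, 1, 2))  # (S,)
        sd = self.priors.beta_sd
        dlp = -0.5 * (((cur + db) / sd) ** 2 - (cur / sd) ** 2)
        acc = self._mh_accept(key, dll + dlp)
        setattr(p, attr, cur + db * acc)
        acc_b = acc[None, None, None, :]
        self.x = np.where(acc_b, x2, self.x)
        self.sp_x = np.where(acc_b, sp2, self.sp_x)

    def update_betas(self) -> None:
        cov = self.cov
        self._update_beta("bd", "beta_date", cov.date[:, :, :, None])
        self._update_beta("bt", "beta_time", cov.time[:, :, :, None])
        self._update_beta("bp", "beta_prevdet", cov.prevdet.astype(np.float64))

    def update_hyper(self) -> None:
        if not self.priors.hierarchical:
            return
        p, h = self.params, self.params.hyper
        rng = self.rng
        sd_upper = self.priors.sd_upper

        def scalar_mh(key_mu, key_sd, values):
            # mu: logistic hyper-prior (flat on probability scale)
            mu, sd = h[key_mu], h[key_sd]
            prop = mu + self.scales[key_mu] * rng.standard_normal()
            delta = (-0.5 * (((values - prop) / sd) ** 2).sum() + _logistic_logpdf(prop)
                     + 0.5 * (((values - mu) / sd) ** 2).sum() - _logistic_logpdf(mu))
            if self._mh_accept(key_mu, np.float64(delta)):
                h[key_mu] = float(prop)
            # sd: U(0, sd_upper)
            mu, sd = h[key_mu], h[key_sd]
            prop = sd + self.scales[key_sd] * rng.standard_normal()
            if 0.0 < prop <= sd_upper:
                n = values.size
                delta = (-n * np.log(prop) - 0.5 * (((values - mu) / prop) ** 2).sum()
                         + n * np.log(sd) + 0.5 * (((values - mu) / sd) ** 2).sum())
                if self._mh_accept(key_sd, np.float64(delta)):
                    h[key_sd] = float(prop)
            else:
                self._mh_accept(key_sd, np.float64(-np.inf))

        scalar_mh("mu_u", "sd_u", p.u)
        if self.T == 2:
            scalar_mh("mu_phi", "sd_phi", self.lphi)
            scalar_mh("mu_gamma", "sd_gamma", self.lgam)

        # year-specific detection hyper-parameters
        mu_v = np.atleast_1d(np.asarray(h["mu_v"], dtype=float)).copy()
        sd_v = np.atleast_1d(np.asarray(h["sd_v"], dtype=float)).copy()
        for t in range(self.T):
            vals = p.v[:, t]
            prop = mu_v[t] + self.scales["mu_v"][t] * rng.standard_normal()
            delta = (-0.5 * (((vals - prop) / sd_v[t]) ** 2).sum() + _logistic_logpdf(prop)
                     + 0.5 * (((vals - mu_v[t]) / sd_v[t]) ** 2).sum() - _logistic_logpdf(mu_v[t]))
            if np.log(rng.random() + 1e-300) < delta:
                mu_v[t] = prop
                self.acc["mu_v"][t] += 1
                self.acc_total["mu_v"][t] += 1
            prop = sd_v[t] + self.scales["sd_v"][t] * rng.standard_normal()
            if 0.0 < prop <= sd_upper:
                n = vals.size
                delta = (-n * np.log(prop) - 0.5 * (((vals - mu_v[t]) / prop) ** 2).sum()
                         + n * np.log(sd_v[t]) + 0.5 * (((vals - mu_v[t]) / sd_v[t]) ** 2).sum())
                if np.log(rng.random() + 1e-300) < delta:
                    sd_v[t] = prop
                    self.acc["sd_v"][t] += 1
                    self.acc_total["sd_v"][t] += 1
        h["mu_v"], h["sd_v"] = mu_v, sd_v

    def adapt(self) -> None:
        batch = max(1, self.n_updates // _ADAPT_INTERVAL)
        delta = min(0.1, batch ** -0.5)
        for key, counts in self.acc.items():
            rate = np.asarray(counts, dtype=float) / _ADAPT_INTERVAL
            adj = np.exp(np.where(rate > _TARGET_ACCEPT, delta, -delta))
            self.scales[key] = np.asarray(self.scales[key]) * adj
            if np.ndim(self.scales[key]) == 0:
                self.scales[key] = float(self.scales[key])
            self.acc[key] = np.zeros_like(rate)

    def sweep(self, adapting: bool) -> None:
        self.update_z()
        self.update_phi_gamma()
        self.update_u()
        self.update_v()
        if self.config.update_betas:
            self.update_betas()
        self.update_hyper()
        if adapting:
            self.n_updates += 1
            if self.n_updates % _ADAPT_INTERVAL == 0:
                self.adapt()


def sample_posterior(det: DetectionArray, cov: SurveyCovariates,
                     priors: PriorConfig | None = None,
                     config: SamplerConfig | None = None,
                     progress: bool = False) -> PosteriorSamples:
    """Run the full posterior simulation and return retained draws.

    Deterministic given ``config.seed``: the same inputs and seed yield
    bit-identical retained draws.
    """
    priors = priors or PriorConfig()
    config = config or SamplerConfig()
    if det.y.size == 0 or not det.surveyed.any():
        raise ValueError("need at least one species and one surveyed site-year")

    never = ~det.y.any(axis=(0, 1, 2))
    if never.any():
        codes = [det.species_codes[i] for i in np.flatnonzero(never)]
        warnings.warn(f"species never detected anywhere: {codes}; "
                      "their occupancy is informed only by the community prior")

    J, T, K, S = det.y.shape
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    n_ret = config.n_retained

    families = {
        "u": (S,), "v": (S, T), "beta_date": (S,), "beta_time": (S,),
        "beta_prevdet": (S,), "phi": (S,), "gamma": (S,),
        "mu_u": (), "sd_u": (), "mu_v": (T,), "sd_v": (T,),
        "mu_phi": (), "sd_phi": (), "mu_gamma": (), "sd_gamma": (),
        "n_occ": (T, S),
    }
    draws = {k: np.empty((config.n_chains, n_ret) + shp) for k, shp in families.items()}
    z_draws = (np.empty((config.n_chains, n_ret, J, T, S), dtype=np.uint8)
               if config.store_z else None)
    acc_rates: list[dict] = []

    for c in range(config.n_chains):
        rng = np.random.Generator(np.random.PCG64(seeds[c]))
        state = _ChainState(det, cov, priors, config, rng)
        lj = log_joint(state.params, LatentOccupancy(state.z.astype(np.uint8)),
                       det, cov, priors)
        if not np.isfinite(lj):
            raise RuntimeError("non-finite log joint density at initialization")
        surveyed = det.surveyed.astype(float)
        r = 0
        for it in range(config.chain_length):
            state.sweep(adapting=it < config.burn_in)
            if it >= config.burn_in and (it - config.burn_in) % config.thin == config.thin - 1:
                p = state.params
                draws["u"][c, r] = p.u
                draws["v"][c, r] = p.v
                draws["beta_date"][c, r] = p.beta_date
                draws["beta_time"][c, r] = p.beta_time
                draws["beta_prevdet"][c, r] = p.beta_prevdet
                draws["phi"][c, r] = p.phi
                draws["gamma"][c, r] = p.gamma
                for hk in ("mu_u", "sd_u", "mu_v", "sd_v", "mu_phi", "sd_phi",
                           "mu_gamma", "sd_gamma"):
                    draws[hk][c, r] = p.hyper[hk]
                draws["n_occ"][c, r] = np.einsum("jt,jts->ts", surveyed, state.z)
                if z_draws is not None:
                    z_draws[c, r] = state.z.astype(np.uint8)
                r += 1
            if progress and (it + 1) % max(1, config.chain_length // 10) == 0:
                print(f"chain {c + 1}/{config.n_chains}: sweep {it + 1}/{config.chain_length}")
        denom = max(config.chain_length, 1)
        acc_rates.append({k: (np.asarray(v) / denom).tolist()
                          for k, v in state.acc_total.items()})

    meta = {
        "config": {"n_chains": config.n_chains, "chain_length": config.chain_length,
                   "burn_in": config.burn_in, "thin": config.thin, "seed": config.seed,
                   "update_betas": config.update_betas},
        "hierarchical": priors.hierarchical,
        "chain_seeds": [int(s.generate_state(1)[0] % (2**31)) for s in seeds],
        "acceptance_rates": acc_rates,
        "shape": {"n_sites": J, "n_years": T, "n_intervals": K, "n_species": S},
        "species_codes": det.species_codes,
        "years": [int(y) for y in det.years],
    }
    return PosteriorSamples(draws=draws, z_draws=z_draws, meta=meta)


def summarize_posterior(samples: PosteriorSamples,
                        probs: tuple[float, float] = (2.5, 97.5)) -> pd.DataFrame:
    """Pooled posterior summaries: mean, SD and percentile interval per
    scalar monitored quantity.  Percentiles use linear interpolation."""
    if samples.n_retained < 1:
        raise ValueError("no retained draws to summarize")
    rows = []
    for name, arr in samples.draws.items():
        flat = arr.reshape(arr.shape[0] * arr.shape[1], -1)
        lo, hi = np.percentile(flat, probs, axis=0)
        means = flat.mean(axis=0)
        sds = flat.std(axis=0, ddof=1) if flat.shape[0] > 1 else np.zeros(flat.shape[1])
        shape = arr.shape[2:]
        for idx in range(flat.shape[1]):
            label = name if not shape else f"{name}[{','.join(map(str, np.unravel_index(idx, shape)))}]"
            rows.append({"param": label, "mean": means[idx], "sd": sds[idx],
                         f"q{probs[0]}": lo[idx], f"q{probs[1]}": hi[idx]})
    return pd.DataFrame(rows)


def save_samples(path: str | Path, samples: PosteriorSamples) -> None:
    """Persist draws as one delimited text file per parameter family plus a
    JSON manifest; ``load_samples`` round-trips losslessly."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    shapes = {}
    for name, arr in samples.draws.items():
        flat = arr.reshape(arr.shape[0] * arr.shape[1], -1)
        np.savetxt(path / f"{name}.txt", flat, delimiter=",", fmt="%.17g")
        shapes[name] = list(arr.shape)
    if samples.z_draws is not None:
        zf = samples.z_draws
        np.savetxt(path / "z.txt", zf.reshape(zf.shape[0] * zf.shape[1], -1),
                   delimiter=",", fmt="%d")
        shapes["z"] = list(zf.shape)
    (path / "manifest.json").write_text(json.dumps({"shapes": shapes, "meta": samples.meta},
                                                   default=str, indent=1))


def load_samples(path: str | Path) -> PosteriorSamples:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    draws = {}
    z_draws = None
    for name, shape in manifest["shapes"].items():
        arr = np.loadtxt(path / f"{name}.txt", delimiter=",", ndmin=2)
        if name == "z":
            z_draws = arr.reshape(shape).astype(np.uint8)
        else:
            draws[name] = arr.reshape(shape)
    return PosteriorSamples(draws=draws, z_draws=z_draws, meta=manifest["meta"])
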