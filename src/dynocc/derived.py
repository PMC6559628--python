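"""Derived change statistics from posterior draws and naive counts.

Per species: change in detectability between primary periods at reference
covariates, occupied-site counts per year (sums of the latent Z matrix over
surveyed sites) and their change, the rate of change in occupancy
lambda = [psi2/(1-psi2)] / [psi1/(1-psi1)] (an occupancy odds ratio),
significance calls from the 95% credible interval, and the across-species
occupancy-detectability correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import DetectionArray
from .model import inv_logit
from .sampler import PosteriorSamples

__all__ = [
    "rate_of_change",
    "occupied_sites",
    "lambda_draws",
    "detectability_change",
    "cri_significant",
    "naive_occupancy",
    "occupancy_detectability_correlation",
    "derived_summary_table",
]


def rate_of_change(psi_t, psi_t1):
    """Occupancy odds ratio between consecutive primary periods.

    Both occupancies must be strictly interior; boundary values make the
    odds ratio undefined and are the caller's responsibility to exclude.
    """
    psi_t = np.asarray(psi_t, dtype=float)
    psi_t1 = np.asarray(psi_t1, dtype=float)
    if np.any((psi_t <= 0) | (psi_t >= 1) | (psi_t1 <= 0) | (psi_t1 >= 1)):
        raise ValueError("rate_of_change requires occupancies strictly in (0, 1)")
    out = (psi_t1 / (1.0 - psi_t1)) / (psi_t / (1.0 - psi_t))
    return out if out.ndim else float(out)


def occupied_sites(samples: PosteriorSamples) -> np.ndarray:
    """Posterior draws of occupied-site counts, shape (n_total_draws, T, S).

    Counts sum the latent state over the sites surveyed in each year, so the
    two years are comparable despite the unbalanced design.
    """
    return samples.pooled("n_occ")


@dataclass
class LambdaDraws:
    """Per-draw occupancy rate-of-change with degenerate draws excluded."""

    values: np.ndarray          # (n_valid, S) masked per species via NaN
    n_excluded: np.ndarray      # (S,) draws with finite-sample psi at 0 or 1


def lambda_draws(samples: PosteriorSamples, det: DetectionArray,
                 parametric: bool = False) -> LambdaDraws:
    """Rate of change in occupancy per posterior draw.

    Default uses finite-sample occupancy (proportion of surveyed sites
    occupied in each year in that draw), which keeps lambda consistent with
    the occupied-site change; ``parametric=True`` uses the model psi instead
    (psi1 from the intercept, psi2 = psi1*phi + (1-psi1)*gamma).
    """
    if parametric:
        psi1 = inv_logit(samples.pooled("u"))
        phi = samples.pooled("phi")
        gam = samples.pooled("gamma")
        psi2 = psi1 * phi + (1 - psi1) * gam
    else:
        n_occ = samples.pooled("n_occ")                    # (N, T, S)
        n_sites = det.surveyed.sum(axis=0).astype(float)   # (T,)
        psi1 = n_occ[:, 0, :] / n_sites[0]
        psi2 = n_occ[:, 1, :] / n_sites[1]
    interior = (psi1 > 0) & (psi1 < 1) & (psi2 > 0) & (psi2 < 1)
    lam = np.full(psi1.shape, np.nan)
    lam[interior] = (psi2[interior] / (1 - psi2[interior])) / (psi1[interior] / (1 - psi1[interior]))
    return LambdaDraws(values=lam, n_excluded=(~interior).sum(axis=0))


def detectability_change(samples: PosteriorSamples) -> np.ndarray:
    """Per-draw change in detection probability (year 2 - year 1) at the
    reference covariate point (standardized date/time 0, no prior detection),
    shape (n_total_draws, S)."""
    v = samples.pooled("v")                                # (N, S, T)
    if v.shape[2] < 2:
        raise ValueError("detectability change needs two primary periods")
    return inv_logit(v[:, :, 1]) - inv_logit(v[:, :, 0])


def cri_significant(draws: np.ndarray, reference: float = 0.0,
                    probs: tuple[float, float] = (2.5, 97.5)) -> tuple[bool, int]:
    """Significance call from the credible interval.

    Returns (significant, direction): significant iff the percentile interval
    excludes the reference; direction is +1 when the interval sits above the
    reference, -1 below, 0 when not significant.
    """
    draws = np.asarray(draws, dtype=float)
    draws = draws[np.isfinite(draws)]
    if draws.size == 0:
        raise ValueError("no draws")
    lo, hi = np.percentile(draws, probs)
    if lo > reference:
        return True, 1
    if hi < reference:
        return True, -1
    return False, 0


def naive_occupancy(det: DetectionArray, species: int, year: int) -> tuple[int, float]:
    """Detection-based (uncorrected) occupancy: number and fraction of
    surveyed sites with at least one detection of the species that year."""
    m = det.surveyed[:, year]
    if not m.any():
        raise ValueError("year has no surveyed sites")
    count = int(det.y[m, year, :, species].any(axis=1).sum())
    return count, count / int(m.sum())


def occupancy_detectability_correlation(mean_p: np.ndarray, mean_psi: np.ndarray,
                                        conf: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Pearson correlation across species of posterior-mean detectability
    vs posterior-mean occupancy, with a Fisher-z confidence interval."""
    mean_p = np.asarray(mean_p, dtype=float)
    mean_psi = np.asarray(mean_psi, dtype=float)
    if mean_p.size < 4:
        raise ValueError("need at least 4 species for a meaningful correlation")
    res = stats.pearsonr(mean_p, mean_psi)
    ci = res.confidence_interval(confidence_level=conf)
    return float(res.statistic), (float(ci.low), float(ci.high))


def derived_summary_table(samples: PosteriorSamples, det: DetectionArray,
                          probs: tuple[float, float] = (2.5, 97.5)) -> pd.DataFrame:
    """Per-species table of the derived quantities with means, credible
    intervals and significance flags, plus naive detection-site counts."""
    S = len(det.species_codes)
    dp = detectability_change(samples)                 # (N, S)
    n_occ = occupied_sites(samples)                    # (N, T, S)
    dn = n_occ[:, 1, :] - n_occ[:, 0, :]
    lam = lambda_draws(samples, det)

    rows = []
    for i, code in enumerate(det.species_codes):
        lam_i = lam.values[:, i]
        lam_i = lam_i[np.isfinite(lam_i)]
        sig_dp, dir_dp = cri_significant(dp[:, i], 0.0, probs)
        sig_dn, dir_dn = cri_significant(dn[:, i], 0.0, probs)
        if lam_i.size:
            sig_lam, dir_lam = cri_significant(lam_i, 1.0, probs)
            lam_mean = lam_i.mean()
            lam_lo, lam_hi = np.percentile(lam_i, probs)
        else:
            sig_lam, dir_lam = False, 0
            lam_mean = lam_lo = lam_hi = np.nan
        naive1 = naive_occupancy(det, i, 0)
        naive2 = naive_occupancy(det, i, det.n_years - 1)
        rows.append({
            "species_code": code,
            "delta_p_mean": dp[:, i].mean(),
            "delta_p_lo": np.percentile(dp[:, i], probs[0]),
            "delta_p_hi": np.percentile(dp[:, i], probs[1]),
            "delta_p_significant": sig_dp, "delta_p_direction": dir_dp,
            "n_occ_year1_mean": n_occ[:, 0, i].mean(),
            "n_occ_year2_mean": n_occ[:, 1, i].mean(),
            "delta_n_occ_mean": dn[:, i].mean(),
            "delta_n_occ_lo": np.percentile(dn[:, i], probs[0]),
            "delta_n_occ_hi": np.percentile(dn[:, i], probs[1]),
            "delta_n_occ_significant": sig_dn, "delta_n_occ_direction": dir_dn,
            "lambda_mean": lam_mean, "lambda_lo": lam_lo, "lambda_hi": lam_hi,
            "lambda_significant": sig_lam, "lambda_direction": dir_lam,
            "lambda_excluded_draws": int(lam.n_excluded[i]),
            "naive_sites_year1": naive1[0], "naive_frac_year1": naive1[1],
            "naive_sites_year2": naive2[0], "naive_frac_year2": naive2[1],
        })
    return pd.DataFrame(rows)
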