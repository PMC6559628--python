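"""Synthetic community generator.

Simulates species-level parameters from community hyper-distributions and
detection histories from the same dynamic occupancy model the sampler fits,
including the study-style unbalanced two-winter design (a block of sites
surveyed in both years plus blocks accessible in only one year).  The
previous-detection covariate is built sequentially within each visit, so the
generator matches the fitted model's covariate definition exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DetectionArray, SurveyCovariates, standardize_covariates
from .model import CommunityParams, LatentOccupancy, inv_logit, logit

__all__ = [
    "SimDesign",
    "CommunityHyper",
    "study_mimic_design",
    "generate_community",
    "write_csvs",
]


@dataclass
class SimDesign:
    """Site/visit layout of a two-winter survey."""

    n_sites_both: int = 186
    n_sites_year1_only: int = 25
    n_sites_year2_only: int = 16
    n_intervals: int = 4
    n_species: int = 35
    n_years: int = 2

    def __post_init__(self) -> None:
        if min(self.n_sites_both, self.n_sites_year1_only, self.n_sites_year2_only) < 0:
            raise ValueError("site counts must be non-negative")
        if self.n_intervals < 1:
            raise ValueError("need at least one secondary interval")

    @property
    def n_sites(self) -> int:
        return self.n_sites_both + self.n_sites_year1_only + self.n_sites_year2_only

    def surveyed_mask(self) -> np.ndarray:
        m = np.zeros((self.n_sites, self.n_years), dtype=bool)
        b, o1 = self.n_sites_both, self.n_sites_year1_only
        m[:b, :] = True
        m[b:b + o1, 0] = True
        m[b + o1:, self.n_years - 1] = True
        return m


@dataclass
class CommunityHyper:
    """Hyper-parameters the species-level effects are drawn from.

    Means of occupancy and detection are given on the probability scale and
    converted to logit-scale normal means; spreads are logit-scale SDs.
    Defaults roughly mimic a diverse forest-bird community: community mean
    occupancy ~0.4 and mean per-interval detectability ~0.3 with logit-scale
    SDs of 1, moderate persistence (0.7) and low colonization (0.2), weak
    date/time effects and a positive previous-detection effect.
    """

    mean_psi: float = 0.4
    sd_u: float = 1.0
    mean_p: float | tuple[float, float] = 0.3
    sd_v: float = 1.0
    mean_phi: float = 0.7
    sd_phi: float = 1.0
    mean_gamma: float = 0.2
    sd_gamma: float = 1.0
    mean_beta_date: float = -0.1
    sd_beta_date: float = 0.3
    mean_beta_time: float = 0.0
    sd_beta_time: float = 0.3
    mean_beta_prevdet: float = 0.5
    sd_beta_prevdet: float = 0.3


def study_mimic_design() -> SimDesign:
    """The deployed design: 186 sites surveyed both winters, 25 in the first
    only, 16 in the second only, four 2.5-minute count intervals, 35 species."""
    return SimDesign(n_sites_both=186, n_sites_year1_only=25, n_sites_year2_only=16,
                     n_intervals=4, n_species=35)


def generate_community(
    hyper: CommunityHyper | None = None,
    design: SimDesign | None = None,
    seed: int = 0,
) -> tuple[CommunityParams, LatentOccupancy, DetectionArray, SurveyCovariates]:
    """Draw a community and a detection history from the generative model.

    Species parameters come from the hyper-distributions; year-1 occupancy
    from psi, year-2 from persistence/colonization dynamics; survey dates are
    uniform over a 90-day season and start times uniform over a morning
    window, constant across the four intervals of a visit, then z-scored over
    surveyed visits; detections are Bernoulli with the sequential
    previous-detection covariate; the unbalanced design mask is applied last.
    """
    hyper = hyper or CommunityHyper()
    design = design or SimDesign(n_sites_both=60, n_sites_year1_only=8,
                                 n_sites_year2_only=6, n_species=10)
    rng = np.random.default_rng(seed)
    J, T, K, S = design.n_sites, design.n_years, design.n_intervals, design.n_species

    u = logit(hyper.mean_psi) + hyper.sd_u * rng.standard_normal(S)
    mean_p = hyper.mean_p if isinstance(hyper.mean_p, tuple) else (hyper.mean_p,) * T
    v = np.column_stack([logit(mp) + hyper.sd_v * rng.standard_normal(S) for mp in mean_p])
    phi = inv_logit(logit(hyper.mean_phi) + hyper.sd_phi * rng.standard_normal(S))
    gamma = inv_logit(logit(hyper.mean_gamma) + hyper.sd_gamma * rng.standard_normal(S))
    bd = hyper.mean_beta_date + hyper.sd_beta_date * rng.standard_normal(S)
    bt = hyper.mean_beta_time + hyper.sd_beta_time * rng.standard_normal(S)
    bp = hyper.mean_beta_prevdet + hyper.sd_beta_prevdet * rng.standard_normal(S)

    params = CommunityParams(
        u=u, v=v, beta_date=bd, beta_time=bt, beta_prevdet=bp, phi=phi, gamma=gamma,
        hyper={"mu_u": logit(hyper.mean_psi), "sd_u": hyper.sd_u,
               "mu_v": np.array([logit(mp) for mp in mean_p]),
               "sd_v": np.full(T, hyper.sd_v),
               "mu_phi": logit(hyper.mean_phi), "sd_phi": hyper.sd_phi,
               "mu_gamma": logit(hyper.mean_gamma), "sd_gamma": hyper.sd_gamma})

    # latent occupancy
    z = np.zeros((J, T, S), dtype=np.uint8)
    z[:, 0, :] = rng.random((J, S)) < inv_logit(u)[None, :]
    for t in range(1, T):
        zp = z[:, t - 1, :]
        psi_t = zp * phi[None, :] + (1 - zp) * gamma[None, :]
        z[:, t, :] = rng.random((J, S)) < psi_t

    surveyed = design.surveyed_mask()

    # raw covariates: one visit per site-year, constant across intervals
    raw_date = np.repeat(rng.uniform(1.0, 90.0, (J, T))[:, :, None], K, axis=2)
    raw_time = np.repeat(rng.uniform(360.0, 660.0, (J, T))[:, :, None], K, axis=2)
    mask3 = np.broadcast_to(surveyed[:, :, None], (J, T, K))
    date, dmean, dsd = standardize_covariates(raw_date, mask3)
    time, tmean, tsd = standardize_covariates(raw_time, mask3)

    # sequential detection process: interval k's detectability depends on
    # whether the species was recorded at k-1
    y = np.zeros((J, T, K, S), dtype=np.uint8)
    prevdet = np.zeros((J, T, K, S), dtype=np.uint8)
    for k in range(K):
        if k > 0:
            prevdet[:, :, k, :] = y[:, :, k - 1, :]
        x = (v.T[None, :, :] + bd[None, None, :] * date[:, :, k, None]
             + bt[None, None, :] * time[:, :, k, None]
             + bp[None, None, :] * prevdet[:, :, k, :])
        p = inv_logit(x)
        y[:, :, k, :] = (rng.random((J, T, S)) < p) & (z == 1) & surveyed[:, :, None]
    prevdet *= surveyed[:, :, None, None]

    det = DetectionArray(
        y=y, surveyed=surveyed,
        site_ids=[f"s{j:04d}" for j in range(J)],
        years=list(range(1, T + 1)),
        species_codes=[f"sp{i:03d}" for i in range(S)],
    )
    cov = SurveyCovariates(
        date=date * mask3, time=time * mask3, prevdet=prevdet,
        constants={"date_mean": dmean, "date_sd": dsd,
                   "time_mean": tmean, "time_sd": tsd,
                   "raw_date": raw_date[:, :, 0].tolist(),
                   "raw_time": raw_time[:, :, 0].tolist()},
    )
    return params, LatentOccupancy(z=z), det, cov


def write_csvs(path: str | Path, params: CommunityParams, zlat: LatentOccupancy,
               det: DetectionArray, cov: SurveyCovariates) -> dict[str, Path]:
    """Write the generated data in the CSV dialects the ingestion layer
    reads (records, visits, species) plus a ground-truth JSON."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    J, T, K, S = det.y.shape
    jj, tt = np.nonzero(det.surveyed)
    rec_rows = []
    for j, t in zip(jj, tt):
        for k in range(K):
            for i in range(S):
                rec_rows.append((det.site_ids[j], det.years[t], k + 1,
                                 det.species_codes[i], int(det.y[j, t, k, i])))
    records = pd.DataFrame(rec_rows, columns=["site_id", "year", "interval",
                                              "species_code", "count"])
    records_path = path / "records.csv"
    records.to_csv(records_path, index=False)

    raw_date = np.asarray(cov.constants["raw_date"])
    raw_time = np.asarray(cov.constants["raw_time"])
    visit_rows = [(det.site_ids[j], det.years[t], k + 1,
                   raw_date[j, t], raw_time[j, t])
                  for j, t in zip(jj, tt) for k in range(K)]
    visits = pd.DataFrame(visit_rows, columns=["site_id", "year", "interval", "date", "time"])
    visits_path = path / "visits.csv"
    visits.to_csv(visits_path, index=False)

    species = pd.DataFrame({"species_code": det.species_codes,
                            "name": det.species_codes,
                            "group": "landbird"})
    species_path = path / "species.csv"
    species.to_csv(species_path, index=False)

    truth = {
        "u": params.u.tolist(), "v": params.v.tolist(),
        "beta_date": params.beta_date.tolist(), "beta_time": params.beta_time.tolist(),
        "beta_prevdet": params.beta_prevdet.tolist(),
        "phi": params.phi.tolist(), "gamma": params.gamma.tolist(),
        "psi1": inv_logit(params.u).tolist(),
        "z_sum": zlat.z.sum(axis=0).tolist(),
        "hyper": {k: (np.asarray(v).tolist()) for k, v in params.hyper.items()},
    }
    truth_path = path / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    return {"records": records_path, "visits": visits_path,
            "species": species_path, "truth": truth_path}
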