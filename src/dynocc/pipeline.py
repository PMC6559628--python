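"""End-to-end orchestration: simulate/ingest -> filter -> fit -> diagnose ->
derive -> report, with a serializable YAML config, per-stage logs and a
manifest of output hashes for provenance."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data as sd
from .derived import derived_summary_table
from .diagnostics import diagnostics_report
from .model import PriorConfig
from .sampler import SamplerConfig, sample_posterior, save_samples, summarize_posterior
from .simulate import CommunityHyper, SimDesign, generate_community, study_mimic_design, write_csvs

__all__ = ["RunConfig", "run_pipeline", "report_tables", "load_config"]

log = logging.getLogger("dynocc")


@dataclass
class RunConfig:
    """Complete, serializable description of one pipeline run."""

    out_dir: str = "run"
    seed: int = 1
    # input mode: "simulate" or paths to CSVs
    simulate: bool = True
    design: str = "small"                      # "small" | "study-mimic" | custom dict
    design_params: dict = field(default_factory=dict)
    hyper_params: dict = field(default_factory=dict)
    records: str | None = None
    visits: str | None = None
    species: str | None = None
    # filtering
    min_site_fraction: float = 0.05
    excluded_groups: list[str] = field(default_factory=lambda: ["raptor", "waterbird"])
    # priors and sampler
    hierarchical: bool = True
    n_chains: int = 3
    chain_length: int = 2000
    burn_in: int = 500
    thin: int = 2
    update_betas: bool = True
    # reporting
    cri_probs: list[float] = field(default_factory=lambda: [2.5, 97.5])
    rhat_threshold: float = 1.1
    bayes_p_max_draws: int = 300

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_yaml(path)


def _design_from_config(cfg: RunConfig) -> SimDesign:
    if cfg.design == "study-mimic":
        return study_mimic_design()
    if cfg.design == "small":
        return SimDesign(n_sites_both=30, n_sites_year1_only=4, n_sites_year2_only=3,
                         n_species=5, **cfg.design_params)
    return SimDesign(**cfg.design_params)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage, writing artifacts and logs under ``cfg.out_dir``.

    Any stage failure raises with the stage named; artifacts written before
    the failure are retained for debugging.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "setup"
    timings: dict[str, float] = {}
    try:
        cfg.to_yaml(out / "config.yaml")

        stage = "ingest"
        t0 = time.perf_counter()
        if cfg.simulate:
            design = _design_from_config(cfg)
            hyper = CommunityHyper(**cfg.hyper_params)
            truth, zlat, det, cov = generate_community(hyper, design, seed=cfg.seed)
            write_csvs(out / "data", truth, zlat, det, cov)
            records = sd.read_records(out / "data" / "records.csv")
            visits = sd.read_visits(out / "data" / "visits.csv")
            species_df = sd.read_species(out / "data" / "species.csv")
        else:
            for name in ("records", "visits", "species"):
                if getattr(cfg, name) is None:
                    raise FileNotFoundError(f"missing required input path: {name}")
            records = sd.read_records(cfg.records)
            visits = sd.read_visits(cfg.visits)
            species_df = sd.read_species(cfg.species)
        det = sd.build_detection_array(records, species_registry=list(species_df["species_code"].astype(str)))
        timings[stage] = time.perf_counter() - t0
        log.info("ingested %d sites x %d years x %d species", det.n_sites, det.n_years, det.n_species)

        stage = "filter"
        t0 = time.perf_counter()
        det, species_tab = sd.filter_species(det, sd.SpeciesTable(species_df),
                                             cfg.min_site_fraction, set(cfg.excluded_groups))
        cov = sd.build_covariates(det, visits)
        sd.save_bundle(out / "arrays", det, cov, species_tab)
        timings[stage] = time.perf_counter() - t0
        log.info("retained %d species after filtering", det.n_species)

        stage = "fit"
        t0 = time.perf_counter()
        sampler_cfg = SamplerConfig(n_chains=cfg.n_chains, chain_length=cfg.chain_length,
                                    burn_in=cfg.burn_in, thin=cfg.thin, seed=cfg.seed,
                                    update_betas=cfg.update_betas)
        priors = PriorConfig(hierarchical=cfg.hierarchical)
        samples = sample_posterior(det, cov, priors, sampler_cfg)
        save_samples(out / "posterior", samples)
        summary = summarize_posterior(samples, tuple(cfg.cri_probs))
        summary.to_csv(out / "posterior_summary.csv", index=False)
        timings[stage] = time.perf_counter() - t0
        log.info("fit complete: %d retained draws x %d chains",
                 samples.n_retained, samples.n_chains)

        stage = "diagnostics"
        t0 = time.perf_counter()
        report = diagnostics_report(samples, det, cov, seed=cfg.seed,
                                    rhat_threshold=cfg.rhat_threshold,
                                    max_draws=cfg.bayes_p_max_draws)
        report.table.to_csv(out / "diagnostics.csv", index=False)
        diag_text = (f"max rhat: {report.table['rhat'].max():.4f}\n"
                     f"min ess: {report.table['ess'].min():.1f}\n"
                     f"flagged params: {int(report.table['flagged'].sum())}\n"
                     f"Bayesian p-value (pooled): {report.bayes_p:.3f}\n"
                     f"Bayesian p-value (mean over species): {report.mean_species_bayes_p:.3f}\n")
        (out / "diagnostics.txt").write_text(diag_text)
        timings[stage] = time.perf_counter() - t0
        log.info("diagnostics: %s", diag_text.replace("\n", "; "))

        stage = "derived"
        t0 = time.perf_counter()
        table = derived_summary_table(samples, det, tuple(cfg.cri_probs))
        table.to_csv(out / "derived_stats.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "manifest"
        files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
        manifest = {
            "config_hash": hashlib.sha256((out / "config.yaml").read_bytes()).hexdigest(),
            "seed": cfg.seed,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "files": {str(p.relative_to(out)): _hash_file(p) for p in files},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return out
    except Exception as exc:
        log.error("pipeline failed at stage '%s': %s", stage, exc)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def report_tables(run_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Collect the per-species report tables from a completed run directory.

    Raises naming any missing upstream artifact.
    """
    run_dir = Path(run_dir)
    needed = {"derived": run_dir / "derived_stats.csv",
              "summary": run_dir / "posterior_summary.csv",
              "diagnostics": run_dir / "diagnostics.csv"}
    missing = [str(p) for p in needed.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing upstream artifacts: {missing}")
    return {k: pd.read_csv(p) for k, p in needed.items()}
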