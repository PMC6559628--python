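"""Survey-data ingestion: long-format point-count records to model-ready arrays.

Counts are collapsed to detection/non-detection on ingestion: the occupancy
model uses only whether a species was recorded during each secondary count
interval, not how many individuals were seen.  Site-years without any survey
records are masked as missing rather than zero-filled, which is how the
unbalanced two-year design (sites surveyed in only one of the two winters)
enters the likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DetectionArray",
    "SpeciesTable",
    "SurveyCovariates",
    "read_records",
    "read_visits",
    "read_species",
    "build_detection_array",
    "filter_species",
    "compute_prevdet",
    "standardize_covariates",
    "build_covariates",
    "save_bundle",
    "load_bundle",
]

RECORD_COLUMNS = ["site_id", "year", "interval", "species_code", "count"]
VISIT_COLUMNS = ["site_id", "year", "interval", "date", "time"]
SPECIES_COLUMNS = ["species_code", "name", "group"]


@dataclass
class DetectionArray:
    """Binary detections ``y[site, year, interval, species]`` plus survey mask.

    ``surveyed[site, year]`` is True only for site-years with at least one
    record; ``y`` is guaranteed zero wherever ``surveyed`` is False.
    """

    y: np.ndarray                 # (J, T, K, S) uint8 in {0, 1}
    surveyed: np.ndarray          # (J, T) bool
    site_ids: list[str]
    years: list[int]
    species_codes: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.uint8)
        self.surveyed = np.asarray(self.surveyed, dtype=bool)
        J, T, K, S = self.y.shape
        if self.surveyed.shape != (J, T):
            raise ValueError("surveyed mask shape does not match y")
        if len(self.site_ids) != J or len(self.years) != T or len(self.species_codes) != S:
            raise ValueError("registry lengths inconsistent with y dimensions")
        if np.any(self.y[~self.surveyed]):
            raise ValueError("detections recorded at unsurveyed site-years")

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_years(self) -> int:
        return self.y.shape[1]

    @property
    def n_intervals(self) -> int:
        return self.y.shape[2]

    @property
    def n_species(self) -> int:
        return self.y.shape[3]

    def sites_surveyed(self, year_index: int) -> int:
        return int(self.surveyed[:, year_index].sum())


@dataclass
class SpeciesTable:
    """Species registry with exclusion groups and per-species site fractions."""

    table: pd.DataFrame  # columns: species_code, name, group, site_fraction

    def __post_init__(self) -> None:
        missing = {"species_code", "name", "group"} - set(self.table.columns)
        if missing:
            raise ValueError(f"species table missing columns: {sorted(missing)}")

    @property
    def codes(self) -> list[str]:
        return list(self.table["species_code"])


@dataclass
class SurveyCovariates:
    """Standardized date/time per (site, year, interval) and the
    previous-interval detection indicator per species.

    ``prevdet[j, t, k, i]`` is 1 when species *i* was detected during the
    immediately preceding count interval of the same visit, and 0 for the
    first interval.  Date and time are z-scored over surveyed visits;
    the constants needed to back-transform are retained.
    """

    date: np.ndarray              # (J, T, K) float, 0 where unsurveyed
    time: np.ndarray              # (J, T, K) float
    prevdet: np.ndarray           # (J, T, K, S) uint8
    constants: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.prevdet[:, :, 0, :]):
            raise ValueError("prevdet must be 0 at the first interval")


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file missing columns: {sorted(missing)}")
    if (df["count"] < 0).any():
        raise ValueError("negative counts in records")
    return df


def read_visits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(VISIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"visits file missing columns: {sorted(missing)}")
    return df


def read_species(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SPECIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"species file missing columns: {sorted(missing)}")
    return df


def build_detection_array(
    records: pd.DataFrame,
    site_registry: list[str] | None = None,
    species_registry: list[str] | None = None,
    n_intervals: int = 4,
) -> DetectionArray:
    """Collapse count records to the binary array y(j, t, k, i).

    Any positive count maps to a detection.  A site-year is flagged surveyed
    iff at least one record (including explicit zero counts) exists for it.
    Duplicate (site, year, interval, species) keys with conflicting counts
    raise; exact duplicates are tolerated.
    """
    records = records.copy()
    sites = site_registry if site_registry is not None else sorted(records["site_id"].astype(str).unique())
    species = species_registry if species_registry is not None else sorted(records["species_code"].astype(str).unique())
    years = sorted(records["year"].unique())

    site_idx = {s: j for j, s in enumerate(sites)}
    sp_idx = {s: i for i, s in enumerate(species)}
    year_idx = {y: t for t, y in enumerate(years)}

    unknown_sites = set(records["site_id"].astype(str)) - set(sites)
    if unknown_sites:
        raise ValueError(f"unknown site identifiers: {sorted(unknown_sites)[:5]}")
    unknown_sp = set(records["species_code"].astype(str)) - set(species)
    if unknown_sp:
        raise ValueError(f"unknown species identifiers: {sorted(unknown_sp)[:5]}")
    bad = ~records["interval"].isin(range(1, n_intervals + 1))
    if bad.any():
        raise ValueError("interval outside 1..%d in records" % n_intervals)

    key = ["site_id", "year", "interval", "species_code"]
    conflict = records.groupby(key)["count"].nunique()
    conflict = conflict[conflict > 1]
    if len(conflict):
        raise ValueError(f"conflicting duplicate records at key {conflict.index[0]}")

    J, T, K, S = len(sites), len(years), n_intervals, len(species)
    y = np.zeros((J, T, K, S), dtype=np.uint8)
    surveyed = np.zeros((J, T), dtype=bool)

    j = records["site_id"].astype(str).map(site_idx).to_numpy()
    t = records["year"].map(year_idx).to_numpy()
    k = records["interval"].to_numpy() - 1
    i = records["species_code"].astype(str).map(sp_idx).to_numpy()
    surveyed[j, t] = True
    det = records["count"].to_numpy() > 0
    y[j[det], t[det], k[det], i[det]] = 1

    return DetectionArray(y=y, surveyed=surveyed, site_ids=list(map(str, sites)),
                          years=list(years), species_codes=list(map(str, species)))


def site_fractions(det: DetectionArray) -> np.ndarray:
    """Fraction of sites (union over years) at which each species was detected."""
    any_site = det.surveyed.any(axis=1)           # sites with data in >= 1 year
    detected = det.y.any(axis=(1, 2))             # (J, S)
    return detected[any_site].mean(axis=0)


def filter_species(
    det: DetectionArray,
    species: SpeciesTable,
    min_site_fraction: float = 0.05,
    excluded_groups: set[str] = frozenset({"raptor", "waterbird"}),
) -> tuple[DetectionArray, SpeciesTable]:
    """Apply the community inclusion rule: drop species detected on fewer than
    ``min_site_fraction`` of sites and species in excluded survey groups."""
    if not 0.0 <= min_site_fraction <= 1.0:
        raise ValueError("min_site_fraction must lie in [0, 1]")
    tab = species.table.set_index("species_code").loc[det.species_codes].reset_index()
    frac = site_fractions(det)
    tab = tab.assign(site_fraction=frac)
    keep = (tab["site_fraction"] >= min_site_fraction) & ~tab["group"].isin(excluded_groups)
    if not keep.any():
        raise ValueError("no species retained; review min_site_fraction / excluded groups")
    idx = np.flatnonzero(keep.to_numpy())
    new_det = DetectionArray(
        y=det.y[:, :, :, idx],
        surveyed=det.surveyed,
        site_ids=det.site_ids,
        years=det.years,
        species_codes=[det.species_codes[i] for i in idx],
    )
    return new_det, SpeciesTable(tab.loc[keep].reset_index(drop=True))


def compute_prevdet(det: DetectionArray) -> np.ndarray:
    """Previous-interval detection indicator: prevdet[..., k, :] = y[..., k-1, :]."""
    prevdet = np.zeros_like(det.y)
    prevdet[:, :, 1:, :] = det.y[:, :, :-1, :]
    return prevdet


def standardize_covariates(raw: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Z-score ``raw`` over entries where ``mask`` is True; zeros elsewhere.

    Returns (standardized, mean, sd).  Raises on zero variance.
    """
    raw = np.asarray(raw, dtype=float)
    vals = raw[mask]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite covariate values on surveyed visits")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    if sd == 0.0:
        raise ValueError("zero variance in covariate; cannot standardize")
    out = np.zeros_like(raw)
    out[mask] = (raw[mask] - mean) / sd
    return out, mean, sd


def build_covariates(det: DetectionArray, visits: pd.DataFrame) -> SurveyCovariates:
    """Assemble standardized date/time plus prevdet from a visits table.

    ``visits`` has one row per (site_id, year, interval) with raw ``date``
    (day of season) and ``time`` (minutes since midnight).
    """
    J, T, K, _ = det.y.shape
    site_idx = {s: j for j, s in enumerate(det.site_ids)}
    year_idx = {y: t for t, y in enumerate(det.years)}
    raw_date = np.zeros((J, T, K))
    raw_time = np.zeros((J, T, K))
    have = np.zeros((J, T, K), dtype=bool)
    j = visits["site_id"].astype(str).map(site_idx)
    if j.isna().any():
        raise ValueError("visits reference unknown sites")
    t = visits["year"].map(year_idx)
    k = visits["interval"].to_numpy() - 1
    raw_date[j.to_numpy(int), t.to_numpy(int), k] = visits["date"].to_numpy(float)
    raw_time[j.to_numpy(int), t.to_numpy(int), k] = visits["time"].to_numpy(float)
    have[j.to_numpy(int), t.to_numpy(int), k] = True

    mask = np.broadcast_to(det.surveyed[:, :, None], (J, T, K))
    if not np.all(have[mask]):
        raise ValueError("missing visit covariates for surveyed site-years")

    date, dmean, dsd = standardize_covariates(raw_date, mask)
    time, tmean, tsd = standardize_covariates(raw_time, mask)
    return SurveyCovariates(
        date=date,
        time=time,
        prevdet=compute_prevdet(det),
        constants={"date_mean": dmean, "date_sd": dsd, "time_mean": tmean, "time_sd": tsd},
    )


def save_bundle(path: str | Path, det: DetectionArray, cov: SurveyCovariates,
                species: SpeciesTable | None = None) -> None:
    """Write the validated arrays as an archival directory of delimited text
    plus a JSON sidecar of registries and standardization constants."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    J, T, K, S = det.y.shape
    np.savetxt(path / "y.txt", det.y.reshape(J, -1), fmt="%d", delimiter=",")
    np.savetxt(path / "surveyed.txt", det.surveyed.astype(int), fmt="%d", delimiter=",")
    np.savetxt(path / "date.txt", cov.date.reshape(J, -1), delimiter=",")
    np.savetxt(path / "time.txt", cov.time.reshape(J, -1), delimiter=",")
    np.savetxt(path / "prevdet.txt", cov.prevdet.reshape(J, -1), fmt="%d", delimiter=",")
    sidecar = {
        "site_ids": det.site_ids,
        "years": [int(y) for y in det.years],
        "species_codes": det.species_codes,
        "n_intervals": K,
        "constants": cov.constants,
    }
    (path / "registries.json").write_text(json.dumps(sidecar, indent=1))
    if species is not None:
        species.table.to_csv(path / "species.csv", index=False)


def load_bundle(path: str | Path) -> tuple[DetectionArray, SurveyCovariates]:
    path = Path(path)
    sidecar = json.loads((path / "registries.json").read_text())
    J = len(sidecar["site_ids"])
    T = len(sidecar["years"])
    K = sidecar["n_intervals"]
    S = len(sidecar["species_codes"])
    y = np.loadtxt(path / "y.txt", delimiter=",", ndmin=2).reshape(J, T, K, S).astype(np.uint8)
    surveyed = np.loadtxt(path / "surveyed.txt", delimiter=",", ndmin=2).astype(bool)
    date = np.loadtxt(path / "date.txt", delimiter=",", ndmin=2).reshape(J, T, K)
    time = np.loadtxt(path / "time.txt", delimiter=",", ndmin=2).reshape(J, T, K)
    prevdet = np.loadtxt(path / "prevdet.txt", delimiter=",", ndmin=2).reshape(J, T, K, S).astype(np.uint8)
    det = DetectionArray(y=y, surveyed=surveyed, site_ids=sidecar["site_ids"],
                         years=sidecar["years"], species_codes=sidecar["species_codes"])
    cov = SurveyCovariates(date=date, time=time, prevdet=prevdet, constants=sidecar["constants"])
    return det, cov
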