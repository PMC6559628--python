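import numpy as np
import pytest

import dynocc
from dynocc.simulate import CommunityHyper, SimDesign


@pytest.fixture(scope="session")
def small_sim():
    """A small unbalanced community simulation shared across tests."""
    design = SimDesign(n_sites_both=40, n_sites_year1_only=5, n_sites_year2_only=4,
                       n_species=6)
    return dynocc.generate_community(CommunityHyper(), design, seed=42)


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A short hierarchical fit of the small simulation (shared; read-only)."""
    _, _, det, cov = small_sim
    cfg = dynocc.SamplerConfig(n_chains=2, chain_length=800, burn_in=300, thin=2, seed=9)
    with np.errstate(all="ignore"):
        samples = dynocc.sample_posterior(det, cov, dynocc.PriorConfig(), cfg)
    return samples


@pytest.fixture()
def tiny_det():
    """Three sites, one year, two intervals, one species."""
    y = np.zeros((3, 1, 2, 1), dtype=np.uint8)
    y[0, 0, :, 0] = [1, 0]
    y[2, 0, :, 0] = [1, 1]
    return dynocc.DetectionArray(y=y, surveyed=np.ones((3, 1), bool),
                                 site_ids=["a", "b", "c"], years=[2015],
                                 species_codes=["sp1"])


@pytest.fixture()
def tiny_cov(tiny_det):
    return dynocc.SurveyCovariates(date=np.zeros((3, 1, 2)), time=np.zeros((3, 1, 2)),
                                   prevdet=dynocc.compute_prevdet(tiny_det))
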