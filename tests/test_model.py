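"""Probability model: psi/p link functions, z full conditional, log joint."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dynocc
from dynocc.model import (CommunityParams, LatentOccupancy, PriorConfig,
                          conditional_z_probability, detection_prob, inv_logit,
                          log_joint, logit, occupancy_prob)


def _params(S=1, T=1, **kw):
    base = dict(u=np.zeros(S), v=np.zeros((S, T)), beta_date=np.zeros(S),
                beta_time=np.zeros(S), beta_prevdet=np.zeros(S),
                phi=np.full(S, 0.5), gamma=np.full(S, 0.5),
                hyper={"mu_u": 0.0, "sd_u": 1.0, "mu_v": np.zeros(T),
                       "sd_v": np.ones(T), "mu_phi": 0.0, "sd_phi": 1.0,
                       "mu_gamma": 0.0, "sd_gamma": 1.0})
    base.update(kw)
    return CommunityParams(**base)


class TestOccupancyProb:
    def test_year1_inverse_logit(self):
        assert occupancy_prob(_params(), 0, 0) == pytest.approx(0.5)

    def test_year2_occupied_site_uses_persistence(self):
        p = _params(phi=np.array([0.9]), gamma=np.array([0.25]))
        assert occupancy_prob(p, 0, 1, z_prev=1) == pytest.approx(0.9)
        assert occupancy_prob(p, 0, 1, z_prev=0) == pytest.approx(0.25)

    def test_year2_requires_previous_state(self):
        with pytest.raises(ValueError):
            occupancy_prob(_params(), 0, 1)


class TestDetectionProb:
    def test_reference_point_is_half(self, tiny_cov):
        assert detection_prob(_params(), tiny_cov, 0, 0, 0, 0) == pytest.approx(0.5)

    def test_intercept_back_transform(self, tiny_cov):
        p = _params(v=np.array([[logit(0.2)]]))
        assert detection_prob(p, tiny_cov, 0, 0, 0, 0) == pytest.approx(0.2)

    def test_prevdet_effect(self, tiny_cov):
        # site 2 (index 2) was detected at interval 0, so prevdet = 1 at interval 1
        p = _params(beta_prevdet=np.array([1.0]))
        assert detection_prob(p, tiny_cov, 2, 0, 1, 0) == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-4)
        assert detection_prob(p, tiny_cov, 2, 0, 1, 0) == pytest.approx(0.7311, abs=1e-4)

    def test_monotone_in_coefficient_for_positive_covariate(self, tiny_cov):
        probs = [detection_prob(_params(beta_prevdet=np.array([b])), tiny_cov, 2, 0, 1, 0)
                 for b in (-1.0, 0.0, 1.0, 2.0)]
        assert probs == sorted(probs)


class TestConditionalZ:
    def test_detection_forces_presence(self):
        assert conditional_z_probability(0.3, [0.5] * 4, [0, 1, 0, 0]) == 1.0

    def test_prior_certainty(self):
        assert conditional_z_probability(1.0, [0.5] * 4, [0, 0, 0, 0]) == 1.0

    def test_exact_arithmetic_all_zero_history(self):
        # psi (1-p)^4 / (psi (1-p)^4 + 1-psi) with psi = p = 0.5 -> 1/17
        got = conditional_z_probability(0.5, [0.5] * 4, [0] * 4)
        assert got == pytest.approx(1 / 17, abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(0.001, 0.999),
           st.lists(st.floats(0.001, 0.999), min_size=1, max_size=5),
           st.data())
    def test_matches_brute_force_enumeration(self, psi, p_vec, data):
        y_vec = [data.draw(st.integers(0, 1)) for _ in p_vec]
        # brute force: joint over z in {0, 1}
        def lik(z):
            prior = psi if z else 1 - psi
            obs = 1.0
            for p, y in zip(p_vec, y_vec):
                pr = p * z
                obs *= pr if y else 1 - pr
            return prior * obs
        expected = lik(1) / (lik(1) + lik(0))
        assert conditional_z_probability(psi, p_vec, y_vec) == pytest.approx(expected, abs=1e-12)


class TestLogJoint:
    def test_detection_without_occupancy_impossible(self, tiny_det, tiny_cov):
        z = LatentOccupancy(np.zeros((3, 1, 1), dtype=np.uint8))
        assert log_joint(_params(), z, tiny_det, tiny_cov, PriorConfig(hierarchical=False)) == -np.inf

    def test_single_cell_closed_form(self):
        # one surveyed site, one interval: occupancy + detection = log(0.5) + log(0.5)
        y = np.ones((1, 1, 1, 1), dtype=np.uint8)
        det = dynocc.DetectionArray(y=y, surveyed=np.ones((1, 1), bool),
                                    site_ids=["s"], years=[1], species_codes=["sp"])
        cov = dynocc.SurveyCovariates(date=np.zeros((1, 1, 1)), time=np.zeros((1, 1, 1)),
                                      prevdet=np.zeros((1, 1, 1, 1), np.uint8))
        z1 = LatentOccupancy(np.ones((1, 1, 1), dtype=np.uint8))
        priors = PriorConfig(hierarchical=False)
        lj = log_joint(_params(), z1, det, cov, priors)
        # subtract the pure prior contribution (same params, site unsurveyed, z = 0)
        det0 = dynocc.DetectionArray(y=np.zeros_like(y), surveyed=np.zeros((1, 1), bool),
                                     site_ids=["s"], years=[1], species_codes=["sp"])
        z0 = LatentOccupancy(np.zeros((1, 1, 1), dtype=np.uint8))
        prior_part = log_joint(_params(), z0, det0, cov, priors) - np.log(0.5)  # minus its own occ term
        assert lj - prior_part == pytest.approx(np.log(0.5) + np.log(0.5), abs=1e-12)
        assert lj - prior_part == pytest.approx(-1.386294, abs=1e-6)

    def test_data_loglik_additive_over_independent_sites(self, tiny_cov):
        rng = np.random.default_rng(1)
        hist = np.array([1, 0], dtype=np.uint8)
        def make(n_sites):
            y = np.tile(hist.reshape(1, 1, 2, 1), (n_sites, 1, 1, 1))
            det = dynocc.DetectionArray(y=y, surveyed=np.ones((n_sites, 1), bool),
                                        site_ids=[f"s{j}" for j in range(n_sites)],
                                        years=[1], species_codes=["sp"])
            cov = dynocc.SurveyCovariates(date=np.zeros((n_sites, 1, 2)),
                                          time=np.zeros((n_sites, 1, 2)),
                                          prevdet=dynocc.compute_prevdet(det))
            z = LatentOccupancy(np.ones((n_sites, 1, 1), dtype=np.uint8))
            return log_joint(_params(u=np.array([0.3])), z, det, cov,
                             PriorConfig(hierarchical=False))
        lj1, lj2, lj3 = make(1), make(2), make(3)
        assert lj2 - lj1 == pytest.approx(lj3 - lj2, abs=1e-10)

    def test_marginalized_joint_matches_zero_inflated_marginal(self, tiny_det, tiny_cov):
        """Summing exp(log_joint) over all z configurations reproduces the
        marginal likelihood of the detection histories (prior part cancels in
        the ratio between two datasets)."""
        params = _params(u=np.array([logit(0.4)]), v=np.array([[logit(0.3)]]))
        priors = PriorConfig(hierarchical=False)

        def marginal_via_enumeration(det, cov):
            total = 0.0
            for bits in range(8):
                z = LatentOccupancy(np.array([(bits >> j) & 1 for j in range(3)],
                                             dtype=np.uint8).reshape(3, 1, 1))
                lj = log_joint(params, z, det, cov, priors)
                total += np.exp(lj) if np.isfinite(lj) else 0.0
            return total

        def marginal_direct(det):
            psi, p = 0.4, 0.3
            out = 1.0
            for j in range(3):
                hist = det.y[j, 0, :, 0]
                occ = psi * np.prod(p ** hist * (1 - p) ** (1 - hist))
                out *= occ + (1 - psi) * (hist.sum() == 0)
            return out

        y2 = tiny_det.y.copy()
        y2[0, 0, :, 0] = [0, 0]
        det2 = dynocc.DetectionArray(y=y2, surveyed=tiny_det.surveyed,
                                     site_ids=tiny_det.site_ids, years=tiny_det.years,
                                     species_codes=tiny_det.species_codes)
        cov2 = dynocc.SurveyCovariates(date=tiny_cov.date, time=tiny_cov.time,
                                       prevdet=dynocc.compute_prevdet(det2))
        ratio_enum = marginal_via_enumeration(tiny_det, tiny_cov) / marginal_via_enumeration(det2, cov2)
        ratio_direct = marginal_direct(tiny_det) / marginal_direct(det2)
        assert ratio_enum == pytest.approx(ratio_direct, rel=1e-10)

    def test_invariant_to_species_relabeling(self, small_sim):
        params, zlat, det, cov = small_sim
        priors = PriorConfig()
        lj = log_joint(params, zlat, det, cov, priors)
        perm = np.array([3, 0, 5, 1, 4, 2])
        params_p = CommunityParams(
            u=params.u[perm], v=params.v[perm], beta_date=params.beta_date[perm],
            beta_time=params.beta_time[perm], beta_prevdet=params.beta_prevdet[perm],
            phi=params.phi[perm], gamma=params.gamma[perm], hyper=params.hyper)
        det_p = dynocc.DetectionArray(y=det.y[:, :, :, perm], surveyed=det.surveyed,
                                      site_ids=det.site_ids, years=det.years,
                                      species_codes=[det.species_codes[i] for i in perm])
        cov_p = dynocc.SurveyCovariates(date=cov.date, time=cov.time,
                                        prevdet=cov.prevdet[:, :, :, perm])
        z_p = LatentOccupancy(zlat.z[:, :, perm])
        assert log_joint(params_p, z_p, det_p, cov_p, priors) == pytest.approx(lj, rel=1e-12)

    def test_non_finite_parameters_raise(self, tiny_det, tiny_cov):
        bad = _params(u=np.array([np.nan]))
        z = LatentOccupancy(np.ones((3, 1, 1), dtype=np.uint8))
        with pytest.raises(ValueError, match="non-finite"):
            log_joint(bad, z, tiny_det, tiny_cov, PriorConfig(hierarchical=False))


def test_inv_logit_logit_round_trip():
    x = np.linspace(-6, 6, 13)
    assert np.allclose(logit(inv_logit(x)), x, atol=1e-10)
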