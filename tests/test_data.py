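"""Ingestion layer: binary conversion, masking, filtering, covariates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dynocc
from dynocc.data import (SpeciesTable, build_detection_array, compute_prevdet,
                         filter_species, load_bundle, save_bundle, site_fractions,
                         standardize_covariates)


def _records(rows):
    return pd.DataFrame(rows, columns=["site_id", "year", "interval", "species_code", "count"])


class TestBuildDetectionArray:
    def test_positive_count_becomes_detection(self):
        det = build_detection_array(_records([("s1", 2015, 2, "spA", 3)]))
        assert det.y[0, 0, 1, 0] == 1

    def test_zero_count_marks_surveyed_without_detection(self):
        det = build_detection_array(_records([("s1", 2015, 1, "spA", 0)]))
        assert det.surveyed[0, 0] and det.y.sum() == 0

    def test_missing_site_year_is_masked_not_zero_filled(self):
        det = build_detection_array(_records([
            ("s1", 2015, 1, "spA", 1), ("s1", 2018, 1, "spA", 0),
            ("s9", 2015, 1, "spA", 2),
        ]))
        j = det.site_ids.index("s9")
        assert not det.surveyed[j, 1]

    def test_conflicting_duplicates_raise_with_key(self):
        recs = _records([("s1", 2015, 1, "spA", 1), ("s1", 2015, 1, "spA", 0)])
        with pytest.raises(ValueError, match="s1"):
            build_detection_array(recs)

    def test_unknown_species_raises(self):
        with pytest.raises(ValueError, match="unknown species"):
            build_detection_array(_records([("s1", 2015, 1, "spA", 1)]),
                                  species_registry=["spB"])

    @settings(max_examples=25, derandomize=True)
    @given(st.randoms(use_true_random=False))
    def test_order_independent(self, rnd):
        rows = [(f"s{j}", y, k, "spA", c)
                for j in range(3) for y in (2015, 2018) for k in (1, 2)
                for c in [rnd.randint(0, 2)]]
        shuffled = rows[:]
        rnd.shuffle(shuffled)
        a = build_detection_array(_records(rows))
        b = build_detection_array(_records(shuffled))
        assert np.array_equal(a.y, b.y) and np.array_equal(a.surveyed, b.surveyed)

    def test_unbalanced_design_bookkeeping(self):
        design = dynocc.study_mimic_design()
        m = design.surveyed_mask()
        assert m[:, 0].sum() == 211
        assert m[:, 1].sum() == 202
        assert m.shape[0] == 227


class TestFilterSpecies:
    @staticmethod
    def _det_with_fractions(n_sites, hits_per_species, groups):
        S = len(hits_per_species)
        y = np.zeros((n_sites, 1, 2, S), dtype=np.uint8)
        for i, h in enumerate(hits_per_species):
            y[:h, 0, 0, i] = 1
        det = dynocc.DetectionArray(y=y, surveyed=np.ones((n_sites, 1), bool),
                                    site_ids=[f"s{j}" for j in range(n_sites)],
                                    years=[2015], species_codes=[f"sp{i}" for i in range(S)])
        tab = SpeciesTable(pd.DataFrame({"species_code": det.species_codes,
                                         "name": det.species_codes, "group": groups}))
        return det, tab

    def test_threshold_and_groups(self):
        det, tab = self._det_with_fractions(50, [2, 3, 40], ["landbird", "landbird", "raptor"])
        fdet, ftab = filter_species(det, tab, 0.05, {"raptor"})
        # 4% excluded, 6% landbird retained, raptor dropped despite 80%
        assert fdet.species_codes == ["sp1"]
        assert ftab.table["site_fraction"].tolist() == [3 / 50]

    def test_empty_retained_raises(self):
        det, tab = self._det_with_fractions(50, [1, 1], ["landbird", "landbird"])
        with pytest.raises(ValueError, match="threshold|review"):
            filter_species(det, tab, 0.5, set())

    @settings(max_examples=20, derandomize=True)
    @given(st.lists(st.integers(0, 30), min_size=3, max_size=8),
           st.floats(0, 0.5), st.floats(0, 0.5))
    def test_filtering_monotone_in_threshold(self, hits, th1, th2):
        lo, hi = sorted([th1, th2])
        det, tab = self._det_with_fractions(30, hits, ["landbird"] * len(hits))
        def n_kept(th):
            try:
                return filter_species(det, tab, th, set())[0].n_species
            except ValueError:
                return 0
        assert n_kept(hi) <= n_kept(lo)

    def test_site_fraction_over_union_of_years(self):
        # site surveyed only in year 2 still counts in the denominator
        y = np.zeros((4, 2, 1, 1), dtype=np.uint8)
        y[0, 0, 0, 0] = 1
        surveyed = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=bool)
        det = dynocc.DetectionArray(y=y, surveyed=surveyed, site_ids=list("abcd"),
                                    years=[1, 2], species_codes=["sp"])
        assert site_fractions(det)[0] == pytest.approx(0.25)


class TestPrevdet:
    @pytest.mark.parametrize("hist,expected", [
        ((0, 1, 0, 1), (0, 0, 1, 0)),
        ((0, 0, 0, 0), (0, 0, 0, 0)),
        ((1, 1, 1, 1), (0, 1, 1, 1)),
    ])
    def test_shift_by_one_interval(self, hist, expected):
        y = np.array(hist, dtype=np.uint8).reshape(1, 1, 4, 1)
        det = dynocc.DetectionArray(y=y, surveyed=np.ones((1, 1), bool),
                                    site_ids=["s"], years=[1], species_codes=["sp"])
        assert tuple(compute_prevdet(det)[0, 0, :, 0]) == expected

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=4, max_size=4))
    def test_total_identity(self, hist):
        # detections in intervals 1..K-1 each seed exactly one prevdet flag
        y = np.array(hist, dtype=np.uint8).reshape(1, 1, 4, 1)
        det = dynocc.DetectionArray(y=y, surveyed=np.ones((1, 1), bool),
                                    site_ids=["s"], years=[1], species_codes=["sp"])
        pd_ = compute_prevdet(det)
        assert pd_[0, 0, 1:, 0].sum() == y[0, 0, :3, 0].sum()


class TestStandardize:
    def test_closed_form_zscore(self):
        out, mean, sd = standardize_covariates(np.array([10.0, 20.0, 30.0]),
                                               np.ones(3, bool))
        assert out == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)
        assert (mean, sd) == (20.0, pytest.approx(8.1650, abs=1e-4))

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            standardize_covariates(np.full(5, 7.0), np.ones(5, bool))

    def test_mean_zero_sd_one_over_mask(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(50, 9, (6, 2, 4))
        mask = rng.random((6, 2, 4)) < 0.7
        out, _, _ = standardize_covariates(raw, mask)
        assert out[mask].mean() == pytest.approx(0.0, abs=1e-12)
        assert out[mask].std() == pytest.approx(1.0, abs=1e-12)
        assert np.all(out[~mask] == 0)


def test_bundle_round_trip(tmp_path, small_sim):
    _, _, det, cov = small_sim
    save_bundle(tmp_path / "b", det, cov)
    det2, cov2 = load_bundle(tmp_path / "b")
    assert np.array_equal(det.y, det2.y)
    assert np.array_equal(det.surveyed, det2.surveyed)
    assert np.allclose(cov.date, cov2.date)
    assert np.array_equal(cov.prevdet, cov2.prevdet)
    assert det.species_codes == det2.species_codes
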