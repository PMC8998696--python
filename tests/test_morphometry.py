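"""Segmentation, typing and shape measurements against analytic oracles."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk

from conftest import match_truth
from myoquant.morphometry import (
    SHAPE_FACTOR_EPS,
    assign_fiber_types,
    csa_histogram,
    measure_fibers,
    segment_fibers,
    shape_factor,
    type_distribution,
)


class TestSegmentation:
    def test_recovers_planted_fiber_count(self, section_and_truth, analyzed):
        _sec, truth = section_and_truth
        lab, fibers = analyzed
        assert len(fibers) == len(truth.fibers)

    def test_blank_channel_warns_and_returns_no_labels(self):
        with pytest.warns(UserWarning, match="uniform"):
            lab = segment_fibers(np.zeros((64, 64), dtype=np.uint8), 0.5)
        assert lab.max() == 0

    def test_full_boundary_line_splits_region(self):
        img = np.zeros((60, 60), dtype=np.uint8)
        img[[0, -1], :] = 200
        img[:, [0, -1]] = 200
        img[30, :] = 200  # a full dividing line
        lab = segment_fibers(img, 1.0, min_fiber_area=0)
        assert lab.max() == 2

    def test_border_touching_fibers_excluded(self):
        img = np.zeros((60, 60), dtype=np.uint8)
        img[30, :] = 200  # two halves, both open to the border
        lab = segment_fibers(img, 1.0, min_fiber_area=0)
        assert lab.max() == 0


class TestTyping:
    def _two_fiber_map(self):
        lab = np.zeros((40, 40), dtype=np.int32)
        lab[5:15, 5:35] = 1
        lab[25:35, 5:35] = 2
        return lab

    @pytest.mark.parametrize(
        "m1,m2,expected",
        [
            # (fiber1, fiber2) medians per channel
            ((200, 200), (3, 200), ("I", "I-IIA")),
            ((3, 3), (200, 3), ("IIA", "IIX")),
        ],
    )
    def test_primary_rules(self, m1, m2, expected):
        lab = self._two_fiber_map()
        c1 = np.zeros_like(lab, dtype=float)
        c2 = np.zeros_like(lab, dtype=float)
        c1[lab == 1], c1[lab == 2] = m1
        c2[lab == 1], c2[lab == 2] = m2
        types = assign_fiber_types(lab, c1, c2, positivity_threshold=50)
        assert (types[1], types[2]) == expected

    def test_intermediate_mhc2a_is_iia_iix_hybrid(self):
        lab = self._two_fiber_map()
        c1 = np.zeros_like(lab, dtype=float)
        c2 = np.zeros_like(lab, dtype=float)
        c2[lab == 1] = 200.0  # the section's strongly IIA-positive reference
        c2[lab == 2] = 70.0  # positive but < 50% of the IIA level
        types = assign_fiber_types(lab, c1, c2, positivity_threshold=50)
        assert types[1] == "IIA"
        assert types[2] == "IIA-IIX"

    def test_permutation_invariance(self, analyzed, section_and_truth):
        sec, _ = section_and_truth
        lab, _ = analyzed
        perm = np.concatenate([[0], np.random.default_rng(0).permutation(lab.max()) + 1])
        relabeled = perm[lab]
        t1 = assign_fiber_types(lab, sec["mhc1"], sec["mhc2a"])
        t2 = assign_fiber_types(relabeled, sec["mhc1"], sec["mhc2a"])
        for fid, t in t1.items():
            assert t2[int(perm[fid])] == t

    def test_typing_accuracy_on_synthetic_section(self, section_and_truth, analyzed):
        sec, truth = section_and_truth
        lab, fibers = analyzed
        types = assign_fiber_types(lab, sec["mhc1"], sec["mhc2a"])
        true_ids = match_truth(fibers, truth.fibers)
        true_types = truth.fibers.set_index("fiber_id")["fiber_type"]
        acc = np.mean(
            [types[fid] == true_types[tid] for fid, tid in zip(fibers["fiber_id"], true_ids)]
        )
        assert acc >= 0.95


class TestMorphometry:
    def test_shape_factor_closed_forms(self):
        r, s = 3.7, 5.0
        assert shape_factor(2 * np.pi * r, np.pi * r**2) == pytest.approx(1.0)
        assert shape_factor(4 * s, s**2) == pytest.approx(4 / np.pi)

    def test_rasterized_disk_measurements(self):
        lab = np.zeros((256, 256), dtype=np.int32)
        rr, cc = disk((128, 128), 50)
        lab[rr, cc] = 1
        m = measure_fibers(lab, pixel_scale=0.5).iloc[0]
        assert m["csa"] == pytest.approx(np.pi * 25**2, rel=0.02)
        assert m["shape_factor"] == pytest.approx(1.0, rel=0.05)

    def test_rasterized_square_shape_factor(self):
        lab = np.zeros((140, 140), dtype=np.int32)
        lab[20:120, 20:120] = 1
        m = measure_fibers(lab, pixel_scale=1.0).iloc[0]
        assert m["shape_factor"] == pytest.approx(4 / np.pi, rel=0.05)

    def test_degenerate_region_excluded_with_warning(self):
        lab = np.zeros((20, 20), dtype=np.int32)
        lab[5:10, 5:10] = 1
        lab[15, 15] = 2
        with pytest.warns(UserWarning, match="degenerate"):
            m = measure_fibers(lab, 1.0)
        assert m["fiber_id"].tolist() == [1]

    def test_csa_recovery_and_isoperimetric_bound(self, section_and_truth, analyzed):
        _sec, truth = section_and_truth
        _lab, fibers = analyzed
        true_ids = match_truth(fibers, truth.fibers)
        true_csa = truth.fibers.set_index("fiber_id")["csa"].loc[true_ids].to_numpy()
        rel_err = np.abs(fibers["csa"].to_numpy() - true_csa) / true_csa
        assert np.median(rel_err) <= 0.05
        assert (fibers["shape_factor"] >= 1 - SHAPE_FACTOR_EPS).all()

    def test_total_csa_bounded_by_tissue_area(self, section_and_truth, analyzed):
        sec, _ = section_and_truth
        _lab, fibers = analyzed
        tissue_area = sec.shape[0] * sec.shape[1] * sec.pixel_scale**2
        assert fibers["csa"].sum() <= tissue_area


class TestDistributions:
    def test_type_distribution(self):
        rec = pd.DataFrame({"fiber_type": ["I"] * 60 + ["IIA"] * 40})
        d = type_distribution(rec)
        assert d["I"] == pytest.approx(0.6)
        assert d["IIA"] == pytest.approx(0.4)
        single = type_distribution(pd.DataFrame({"fiber_type": ["IIX"]}))
        assert single["IIX"] == 1.0
        with pytest.raises(ValueError):
            type_distribution(pd.DataFrame({"fiber_type": []}))

    def test_csa_histogram_sums_to_one_per_type(self, analyzed):
        _lab, fibers = analyzed
        h = csa_histogram(fibers, bin_width=500.0)
        sums = h.groupby("fiber_type")["frequency"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_single_bin_case(self):
        rec = pd.DataFrame({"fiber_type": ["I", "I"], "csa": [100.0, 110.0]})
        h = csa_histogram(rec, bin_width=500.0)
        assert len(h) == 1
        assert h["frequency"].iloc[0] == pytest.approx(1.0)
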