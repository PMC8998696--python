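"""Protein filtering, differential testing and KS functional class scoring."""

import numpy as np
import pandas as pd
import pytest

from myoquant.synthgen import ProteinTableParams, generate_protein_table
from myoquant.proteome import (
    differential_test,
    filter_complete,
    functional_class_scoring,
    read_gmt,
    write_gmt,
)


class TestFilterComplete:
    def test_rows_with_missing_removed(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.normal(size=(10, 4)), index=[f"P{i}" for i in range(10)])
        t.iloc[2, 1] = np.nan
        t.iloc[7, 3] = np.nan
        out = filter_complete(t)
        assert len(out) == 8
        # brute-force row scan oracle
        expected = [i for i in t.index if not t.loc[i].isna().any()]
        assert list(out.index) == expected

    def test_complete_table_unchanged(self):
        t = pd.DataFrame(np.ones((5, 3)))
        pd.testing.assert_frame_equal(filter_complete(t), t)

    def test_all_missing_rejected(self):
        t = pd.DataFrame({"a": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            filter_complete(t)


class TestDifferential:
    def test_paired_duplicate_samples_give_p_one_or_undefined(self):
        tab, meta, _ = generate_protein_table(
            ProteinTableParams(n_proteins=40, n_diff=0, seed=3)
        )
        g = meta[meta.group == "37Y"].copy()
        # overwrite POST with PRE values: no within-subject change at all
        for subj in g.subject.unique():
            pre = g[(g.subject == subj) & (g.time == "PRE")]["sample"].iloc[0]
            post = g[(g.subject == subj) & (g.time == "POST")]["sample"].iloc[0]
            tab[post] = tab[pre]
        d = differential_test(tab[g["sample"]], g, ("time", "POST", "PRE"), paired=True)
        assert ((d["p"].fillna(1.0) > 0.999) | d["undefined"]).all()

    def test_planted_proteins_detected(self):
        """Strongly shifted proteins survive 400-way FDR correction."""
        detected = []
        for seed in range(5):
            p = ProteinTableParams(
                n_proteins=400, n_subjects_per_group=6, n_diff=4,
                effect_size=2.5, noise_sd=0.5, effect_on="group", seed=seed,
            )
            tab, meta, truth = generate_protein_table(p)
            pre = meta[meta.time == "PRE"]
            d = differential_test(tab[pre["sample"]], pre, ("group", "50Y", "37Y"))
            tp = set(truth[truth.label == "diff"].protein)
            detected.append(len(set(d[d.significant].protein) & tp))
        assert np.mean(detected) >= 3

    def test_column_order_invariance(self):
        tab, meta, _ = generate_protein_table(ProteinTableParams(n_proteins=30, seed=4))
        pre = meta[meta.time == "PRE"]
        a = differential_test(tab[pre["sample"]], pre, ("group", "50Y", "37Y"))
        shuffled = tab[list(tab.columns[::-1])]
        b = differential_test(shuffled[pre["sample"]], pre, ("group", "50Y", "37Y"))
        np.testing.assert_allclose(a["p"], b["p"])

    def test_correction_ordering(self):
        tab, meta, _ = generate_protein_table(
            ProteinTableParams(n_proteins=100, n_diff=5, effect_size=1.5, seed=5)
        )
        g = meta[meta.group == "37Y"]
        args = (tab[g["sample"]], g, ("time", "POST", "PRE"))
        bh = differential_test(*args, paired=True, correction="BH")
        by = differential_test(*args, paired=True, correction="BY")
        assert (by["p_adj"] >= bh["p_adj"] - 1e-12).all()
        assert (bh["p_adj"] >= bh["p"] - 1e-12).all()


class TestFCS:
    def _ranking(self, n=50):
        return pd.DataFrame(
            {"protein": [f"P{i:04d}" for i in range(1, n + 1)], "stat": np.arange(n, 0, -1.0)}
        )

    def test_whole_universe_set_is_null(self):
        rk = self._ranking()
        out = functional_class_scoring(rk, {"all": rk["protein"].tolist()})
        assert out["ks"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_top_k_set_matches_brute_force_ecdf_supremum(self):
        rk = self._ranking(40)
        k = 8
        members = rk["protein"].iloc[:k].tolist()
        out = functional_class_scoring(rk, {"top": members})
        in_ranks = np.arange(1, k + 1)
        out_ranks = np.arange(k + 1, 41)
        # brute-force two-sample ECDF supremum over all thresholds
        grid = np.arange(0, 42)
        sup = max(
            abs((in_ranks <= x).mean() - (out_ranks <= x).mean()) for x in grid
        )
        assert out["ks"].iloc[0] == pytest.approx(sup)
        assert out["direction"].iloc[0] == "enriched"

    def test_invariant_under_monotone_transform_of_statistic(self):
        rk = self._ranking(30)
        sets = {"s": rk["protein"].iloc[5:15].tolist()}
        a = functional_class_scoring(rk, sets)
        rk2 = rk.assign(stat=np.exp(rk["stat"] / 10))
        b = functional_class_scoring(rk2, sets)
        assert a["ks"].iloc[0] == pytest.approx(b["ks"].iloc[0])
        assert a["p"].iloc[0] == pytest.approx(b["p"].iloc[0])

    def test_small_sets_skipped(self):
        rk = self._ranking(20)
        out = functional_class_scoring(rk, {"tiny": rk["protein"].iloc[:2].tolist()})
        assert len(out) == 0

    def test_planted_set_detected_others_not(self):
        ids = [f"P{i:04d}" for i in range(1, 26)]
        p = ProteinTableParams(
            n_proteins=400, n_subjects_per_group=6, n_diff=0, noise_sd=0.5,
            planted_sets={"oxphos": (ids, 0.6)}, effect_on="time", seed=8,
        )
        tab, meta, truth = generate_protein_table(p)
        g = meta[meta.group == "37Y"]
        d = differential_test(tab[g["sample"]], g, ("time", "POST", "PRE"), paired=True)
        ranking = d[["protein"]].assign(stat=d["t"].abs())
        rng = np.random.default_rng(0)
        decoys = {
            f"decoy{k}": list(rng.choice(tab.index, 25, replace=False)) for k in range(5)
        }
        fcs = functional_class_scoring(ranking, {"oxphos": ids, **decoys}).set_index("set")
        assert fcs.loc["oxphos", "significant"]
        assert not fcs.drop("oxphos")["significant"].any()


def test_gmt_roundtrip(tmp_path):
    sets = {"a": ["P1", "P2", "P3"], "b": ["P2", "P9"]}
    path = tmp_path / "sets.gmt"
    write_gmt(path, sets)
    assert read_gmt(path) == sets
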