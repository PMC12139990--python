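"""Top-target ranking and gold-standard overlap statistics."""

import numpy as np
import pytest

from drugsig.errors import ValidationError
from drugsig.model import Compound, GoldStandardTargets, SignatureMatrix
from drugsig.targets import (
    best_ranks,
    control_drug_sets,
    cross_indication_jaccard,
    jaccard,
    overlap_analysis,
    pooled_prediction_targets,
    top_targets,
)


def matrix(vals, comps, prots):
    return SignatureMatrix(np.asarray(vals, dtype=float), comps, prots)


class TestTopTargets:
    def test_score_ties_broken_by_protein_id(self):
        mat = matrix([[0.2, 0.9, 0.9]], ["D1"], ["A", "B", "C"])
        tt = top_targets("D1", mat, depth=3)
        assert [(t.protein_id, t.rank) for t in tt.targets] == \
               [("B", 1), ("C", 2), ("A", 3)]

    def test_depth_one_returns_single_best(self):
        mat = matrix([[0.2, 0.9, 0.5]], ["D1"], ["A", "B", "C"])
        tt = top_targets("D1", mat, depth=1)
        assert [(t.protein_id, t.score) for t in tt.targets] == [("B", 0.9)]

    def test_matches_brute_force_sort(self, rng):
        prots = [f"P{j:02d}" for j in range(20)]
        vals = rng.random((1, 20))
        mat = matrix(vals, ["D1"], prots)
        tt = top_targets("D1", mat, depth=20)
        want = sorted(zip(prots, vals[0]), key=lambda t: (-t[1], t[0]))
        assert [(t.protein_id, t.score) for t in tt.targets] == \
               [(p, pytest.approx(v)) for p, v in want]
        assert [t.rank for t in tt.targets] == list(range(1, 21))

    def test_unknown_compound_rejected(self):
        mat = matrix([[0.1]], ["D1"], ["A"])
        with pytest.raises(ValidationError):
            top_targets("ZZ", mat)


class TestJaccard:
    @pytest.mark.parametrize("a, b, expected", [
        ({"x", "y"}, {"x", "y"}, 1.0),
        ({"x"}, {"y"}, 0.0),
        ({"a", "b", "c", "d"}, {"c", "d", "e", "f"}, 2 / 6),
        (set(), set(), 0.0),
    ])
    def test_examples(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)
        assert jaccard(b, a) == pytest.approx(expected)
        assert 0.0 <= jaccard(a, b) <= 1.0


class TestPooledTargets:
    def test_single_drug_gives_its_top_k(self):
        mat = matrix([[0.9, 0.8, 0.7, 0.1]], ["D1"], ["A", "B", "C", "D"])
        assert pooled_prediction_targets(["D1"], mat, 3) == {"A", "B", "C"}

    def test_union_is_superset_of_each_drug_set(self, rng):
        mat = matrix(rng.random((4, 10)), [f"D{i}" for i in range(4)],
                     [f"P{j}" for j in range(10)])
        pooled = pooled_prediction_targets([f"D{i}" for i in range(4)], mat, 3)
        for i in range(4):
            assert pooled >= pooled_prediction_targets([f"D{i}"], mat, 3)

    def test_identical_rows_collapse(self):
        row = [0.9, 0.8, 0.7, 0.1, 0.2]
        mat = matrix([row, row], ["D1", "D2"], list("ABCDE"))
        assert len(pooled_prediction_targets(["D1", "D2"], mat, 3)) == 3


class TestOverlapAnalysis:
    def _mat(self):
        # D1 ranks: A(1) B(2) C(3) D(4) E(5); D2 ranks: E(1) D(2) C(3) B(4) A(5)
        return matrix([[0.9, 0.8, 0.7, 0.6, 0.5],
                       [0.5, 0.6, 0.7, 0.8, 0.9]], ["D1", "D2"], list("ABCDE"))

    def test_best_rank_is_minimum_across_drugs(self):
        ranks = best_ranks(["D1", "D2"], self._mat())
        assert ranks == {"A": 1, "B": 2, "C": 3, "D": 2, "E": 1}

    def test_hand_computed_statistics(self):
        gold = GoldStandardTargets("lit", frozenset({"A", "D", "E"}))
        rep = overlap_analysis(["D1", "D2"], gold, self._mat(),
                               bins=((1, 2), (3, 4)), cutoffs=(1, 2, 5),
                               jaccard_cutoff=2, drug_set_label="top")
        # best ranks of gold proteins: A->1, D->2, E->1 : all in bin (1,2)
        assert rep.bin_frequencies == {(1, 2): 1.0, (3, 4): 0.0}
        assert rep.unbinned_fraction == 0.0
        assert rep.cumulative_overlap == {1: pytest.approx(200 / 3),
                                          2: pytest.approx(100.0),
                                          5: pytest.approx(100.0)}
        # pooled rank<=2 targets {A,B,D,E}; gold {A,D,E}: J = 3/4
        assert rep.jaccard == pytest.approx(0.75)

    def test_disjoint_gold_gives_zero_report(self):
        gold = GoldStandardTargets("lit", frozenset({"Z1", "Z2"}))
        rep = overlap_analysis(["D1"], gold, self._mat(), cutoffs=(1, 5))
        assert rep.jaccard == 0.0
        assert all(v == 0.0 for v in rep.cumulative_overlap.values())
        assert rep.unbinned_fraction == 1.0

    def test_gold_equal_to_pooled_targets_gives_full_overlap(self):
        mat = self._mat()
        pooled = pooled_prediction_targets(["D1"], mat, 3)
        rep = overlap_analysis(["D1"], GoldStandardTargets("g", frozenset(pooled)),
                               mat, cutoffs=(3,), jaccard_cutoff=3)
        assert rep.jaccard == 1.0
        assert rep.cumulative_overlap[3] == pytest.approx(100.0)

    def test_cumulative_overlap_nondecreasing_and_bounded(self, rng):
        mat = matrix(rng.random((5, 30)), [f"D{i}" for i in range(5)],
                     [f"P{j:02d}" for j in range(30)])
        gold = GoldStandardTargets("g", frozenset({f"P{j:02d}" for j in range(0, 30, 3)}))
        rep = overlap_analysis([f"D{i}" for i in range(5)], gold, mat,
                               cutoffs=tuple(range(5, 31, 5)))
        vals = list(rep.cumulative_overlap.values())
        assert vals == sorted(vals)
        assert all(0.0 <= v <= 100.0 for v in vals)
        assert abs(sum(rep.bin_frequencies.values()) - 1.0) < 1e-12 or \
            all(v == 0.0 for v in rep.bin_frequencies.values())


class TestControlDrugSets:
    def _candidates(self, n=40):
        comps = {f"C{i:02d}": Compound(id=f"C{i:02d}", heavy_atoms=3 if i % 5 == 0 else 20)
                 for i in range(n)}
        return [f"C{i:02d}" for i in range(n)], comps

    def test_three_sets_of_k(self):
        cand, comps = self._candidates()
        sets = control_drug_sets(cand, comps, k=8, seed=1)
        assert set(sets) == {"top", "random", "bottom"}
        assert all(len(s) == 8 for s in sets.values())
        assert sets["top"] == cand[:8]

    def test_same_seed_same_random_set(self):
        cand, comps = self._candidates()
        a = control_drug_sets(cand, comps, k=8, seed=42)
        b = control_drug_sets(cand, comps, k=8, seed=42)
        assert a["random"] == b["random"]
        c = control_drug_sets(cand, comps, k=8, seed=43)
        assert a["random"] != c["random"]

    def test_small_molecules_never_in_bottom_set(self):
        cand, comps = self._candidates()
        sets = control_drug_sets(cand, comps, k=8, seed=1)
        assert all(comps[cid].heavy_atoms >= 5 for cid in sets["bottom"])
        # bottom set is the tail of the filtered table
        eligible = [c for c in cand if comps[c].heavy_atoms >= 5]
        assert sets["bottom"] == eligible[-8:]

    def test_shortfall_raises(self):
        cand, comps = self._candidates(10)
        with pytest.raises(ValidationError, match="heavy-atom"):
            control_drug_sets(cand, comps, k=9, seed=0)

    def test_unknown_heavy_atom_count_fails_filter(self):
        comps = {f"C{i}": Compound(id=f"C{i}", heavy_atoms=None) for i in range(5)}
        with pytest.raises(ValidationError):
            control_drug_sets([f"C{i}" for i in range(5)], comps, k=2, seed=0)


class TestCrossIndicationJaccard:
    def test_identical_gold_sets_give_identical_columns(self, rng):
        mat = matrix(rng.random((6, 12)), [f"D{i}" for i in range(6)],
                     [f"P{j:02d}" for j in range(12)])
        cands = {"I1": [f"D{i}" for i in range(3)], "I2": [f"D{i}" for i in range(3, 6)]}
        gold = [GoldStandardTargets("g1", frozenset({"P00", "P01"})),
                GoldStandardTargets("g2", frozenset({"P00", "P01"}))]
        df = cross_indication_jaccard(cands, mat, gold, top_ns=(2,), rank_cutoff=4)
        piv = df.pivot(index="indication_id", columns="gold_label", values="jaccard")
        assert (piv["g1"] == piv["g2"]).all()

    def test_empty_candidate_table_gives_zero_row(self, rng):
        mat = matrix(rng.random((2, 4)), ["D0", "D1"], list("ABCD"))
        df = cross_indication_jaccard({"I1": []}, mat,
                                      [GoldStandardTargets("g", frozenset({"A"}))],
                                      top_ns=(24,))
        assert (df["jaccard"] == 0.0).all()
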