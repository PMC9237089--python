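"""Partition scoring: NMI, pairwise IR metrics, pathway ratios, overlaps, grid."""

import math

import numpy as np
import pytest

from orcci import (
    Partition,
    SideInfo,
    nmi,
    overlap_variation,
    pairwise_ir_metrics,
    pathway_protein_ratio,
    run_grid,
    size_classes,
)
from orcci.errors import ConfigError, GraphError
from orcci.synthetic import ExperimentConfig


class TestNMI:
    def test_identity_is_one(self):
        p = Partition({"a": 1, "b": 1, "c": 2, "d": 2})
        assert nmi(p, p) == pytest.approx(1.0)

    def test_single_community_vs_split_is_zero(self):
        p = Partition({"a": 1, "b": 1, "c": 2, "d": 2})
        q = Partition({n: 0 for n in "abcd"})
        assert nmi(p, q) == pytest.approx(0.0)

    def test_both_single_community_defined_as_one(self):
        p = Partition({"a": 0, "b": 0})
        q = Partition({"a": "x", "b": "x"})
        assert nmi(p, q) == 1.0

    def test_hand_contingency_table(self):
        # p = {a,b | c,d}, q = {a,b,c | d}: contingency [[2,0],[1,1]]
        p = Partition({"a": 1, "b": 1, "c": 2, "d": 2})
        q = Partition({"a": 1, "b": 1, "c": 1, "d": 2})
        n = 4
        hp = -(0.5 * math.log(0.5)) * 2
        hq = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        i = (
            (2 / n) * math.log((2 / n) / (0.5 * 0.75))
            + (1 / n) * math.log((1 / n) / (0.5 * 0.75))
            + (1 / n) * math.log((1 / n) / (0.5 * 0.25))
        )
        assert nmi(p, q) == pytest.approx(2 * i / (hp + hq), abs=1e-12)

    def test_symmetric_and_relabel_invariant(self):
        p = Partition({"a": 1, "b": 1, "c": 2, "d": 3})
        q = Partition({"a": "x", "b": "y", "c": "y", "d": "x"})
        assert nmi(p, q) == pytest.approx(nmi(q, p))
        relabeled = Partition({"a": 9, "b": 9, "c": 7, "d": 5})
        assert nmi(relabeled, q) == pytest.approx(nmi(p, q))

    def test_mismatched_universes_raise(self):
        with pytest.raises(GraphError):
            nmi(Partition({"a": 1}), Partition({"b": 1}))


class TestPairwiseIR:
    def test_perfect_detection(self):
        t = Partition({"a": 1, "b": 1, "c": 2, "d": 2})
        m = pairwise_ir_metrics(t, t)
        assert (m.accuracy, m.precision, m.sensitivity, m.f1) == (1, 1, 1, 1)

    def test_all_singletons_zero_sensitivity(self):
        t = Partition({"a": 1, "b": 1, "c": 2, "d": 2})
        d = Partition({n: n for n in "abcd"})
        m = pairwise_ir_metrics(t, d)
        assert m.sensitivity == 0.0
        assert "precision" in m.undefined

    def test_hand_enumerated_pairs(self):
        # truth {a,b | c,d}, detected all together: TP=2, FP=4, FN=0, TN=0
        t = Partition({"a": 1, "b": 1, "c": 2, "d": 2})
        d = Partition({n: 0 for n in "abcd"})
        m = pairwise_ir_metrics(t, d)
        assert m.precision == pytest.approx(1 / 3)
        assert m.sensitivity == pytest.approx(1.0)
        assert m.accuracy == pytest.approx(2 / 6)

    def test_relabel_invariance_and_accuracy_iff_equal(self):
        t = Partition({"a": 1, "b": 1, "c": 2, "d": 2, "e": 3})
        d = Partition({"a": "x", "b": "x", "c": "y", "d": "y", "e": "z"})
        assert pairwise_ir_metrics(t, d).accuracy == 1.0
        d2 = Partition({"a": "x", "b": "x", "c": "y", "d": "z", "e": "z"})
        assert pairwise_ir_metrics(t, d2).accuracy < 1.0

    def test_node_majority_scheme(self):
        t = Partition({"a": 1, "b": 1, "c": 2, "d": 2})
        d = Partition({"a": 0, "b": 0, "c": 0, "d": 9})
        m = pairwise_ir_metrics(t, d, scheme="node_majority")
        # community 0 maps to label 1 (tie 2-vs-1? no: labels 1,1,2 -> 1)
        assert m.accuracy == pytest.approx(3 / 4)

    def test_too_few_nodes_raise(self):
        with pytest.raises(GraphError):
            pairwise_ir_metrics(Partition({"a": 1}), Partition({"a": 1}))


class TestPathwayRatio:
    def test_plurality_and_unannotated_members(self):
        det = Partition({"p1": "c1", "p2": "c1", "p3": "c1"})
        ann = SideInfo.from_dict({"p1": {"Auxin"}, "p2": {"Auxin"}})
        rows, mean = pathway_protein_ratio(det, ann)
        assert rows["c1"].label == "Auxin"
        assert rows["c1"].ratio == pytest.approx(2 / 3)
        assert mean == pytest.approx(2 / 3)

    def test_unannotated_community_excluded(self):
        det = Partition({"p1": "c1", "p2": "c2"})
        ann = SideInfo.from_dict({"p1": {"ET"}})
        rows, mean = pathway_protein_ratio(det, ann)
        assert rows["c2"].ratio is None
        assert mean == pytest.approx(1.0)

    def test_tie_breaks_lexicographically(self):
        det = Partition({"p1": "c", "p2": "c"})
        ann = SideInfo.from_dict({"p1": {"Auxin"}, "p2": {"ABA"}})
        rows, _ = pathway_protein_ratio(det, ann)
        assert rows["c"].label == "ABA"
        assert rows["c"].ratio == pytest.approx(0.5)


class TestSizeClasses:
    @pytest.mark.parametrize(
        "sizes,want",
        [((2, 4, 7), (1, 1, 1)), ((3, 5), (1, 1, 0)), ((), (0, 0, 0)),
         ((1, 1, 3, 4, 5, 6, 25), (3, 2, 2))],
    )
    def test_boundaries(self, sizes, want):
        assignment = {}
        for c, s in enumerate(sizes):
            for k in range(s):
                assignment[f"n{c}_{k}"] = c
        assert size_classes(Partition(assignment)) == want


class TestOverlapVariation:
    def test_exact_match_row(self):
        base = Partition({f"w{i}": "W" for i in range(11)})
        det = Partition({f"w{i}": "D" for i in range(11)})
        rep = overlap_variation(det, base)
        row = rep.rows[0]
        assert row.overlap_ratio == pytest.approx(1.0)
        assert row.variation_ratio == pytest.approx(0.0)

    def test_half_overlap_half_variation(self):
        base = Partition({str(i): "B" for i in (1, 2, 3, 4)})
        det = Partition({str(i): "D" for i in (3, 4, 5, 6)})
        rep = overlap_variation(det, base)
        row = rep.rows[0]
        assert row.overlap_ratio == pytest.approx(0.5)
        assert row.variation_ratio == pytest.approx(0.5)
        assert row.matched_size == row.intersection + 2  # |D| = |DnB| + |D\B|

    def test_disjoint_gives_zero(self):
        base = Partition({"a": "B"})
        det = Partition({"x": "D", "y": "D"})
        rep = overlap_variation(det, base)
        assert rep.rows[0].overlap_ratio == 0.0

    def test_oversized_match_flagged_untestable(self):
        base = Partition({"a": "B", "b": "B"})
        det = Partition({n: "D" for n in ["a", "b"] + [f"x{i}" for i in range(20)]})
        rep = overlap_variation(det, base)
        assert rep.rows[0].untestable
        assert math.isnan(rep.mean_overlap)

    def test_union_and_sum_columns(self):
        base = Partition({str(i): "B" for i in range(6)})
        det = Partition({"0": "D1", "1": "D1", "2": "D2", "3": "D2",
                         "4": "D2", "9": "D1"})
        rep = overlap_variation(det, base)
        row = rep.rows[0]
        assert row.n_overlapping == 2
        assert row.union_size == 6  # D1 u D2
        assert row.sum_size == 6


class TestRunGrid:
    def _tiny(self, **kw):
        base = dict(
            block_sizes=(6, 6),
            p_in=1.0,
            p_out=0.0,
            observability=(1.0,),
            side_info=(0.0,),
            repeats=1,
            seed=3,
        )
        base.update(kw)
        return ExperimentConfig(**base)

    def test_disjoint_cliques_trivially_recovered(self):
        res = run_grid(self._tiny())
        assert (res.rows["nmi"] == 1.0).all()

    def test_row_bookkeeping(self):
        cfg = self._tiny(observability=(0.8, 1.0), side_info=(0.0, 0.5), repeats=2)
        res = run_grid(cfg)
        assert len(res.rows) == 2 * 2 * 2 * 2  # obs x si x repeats x kinds
        assert len(res.summary) == 2 * 2 * 2
        assert res.rows["nmi"].between(0, 1).all()

    def test_reproducible(self):
        cfg = self._tiny(block_sizes=(8, 8), p_in=0.8, p_out=0.05,
                         observability=(0.7,), side_info=(0.3,), repeats=2)
        a, b = run_grid(cfg), run_grid(cfg)
        assert a.rows.equals(b.rows)
        assert a.summary.equals(b.summary)
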