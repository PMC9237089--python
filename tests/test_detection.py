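"""The removal loop: protection, modularity tracking, trace invariants."""

import networkx as nx
import numpy as np
import pytest

from orcci import (
    DetectionConfig,
    Network,
    Partition,
    SideInfo,
    components_partition,
    detect,
    is_protected,
    modularity,
)
from orcci.errors import GraphError, UndefinedModularityError

from .conftest import random_network


class TestProtection:
    def test_shared_label(self):
        si = SideInfo.from_dict({"a": {"Auxin"}, "b": {"Auxin", "ABA"}})
        assert is_protected(("a", "b"), si)

    def test_disjoint_labels(self):
        si = SideInfo.from_dict({"a": {"Auxin"}, "b": {"ET"}})
        assert not is_protected(("a", "b"), si)

    def test_unlabeled_endpoint(self):
        si = SideInfo.from_dict({"a": {"Auxin"}})
        assert not is_protected(("a", "b"), si)
        assert not is_protected(("a", "b"), None)


class TestComponentsPartition:
    def test_two_triangles(self, barbell):
        part = components_partition(barbell.remove_edge("c", "d"))
        assert sorted(map(len, part.communities.values())) == [3, 3]

    def test_connected_graph_single_community(self, barbell):
        assert components_partition(barbell).n_communities == 1

    def test_isolated_nodes_are_singletons(self):
        net = Network.from_edges([], nodes=["a", "b", "c"])
        part = components_partition(net)
        assert part.n_communities == 3

    def test_deterministic_smallest_member_ids(self, barbell):
        part = components_partition(barbell.remove_edge("c", "d"))
        assert set(part.communities) == {"a", "d"}


class TestModularity:
    def test_single_community_zero(self, barbell):
        part = Partition({n: 0 for n in barbell.nodes})
        assert modularity(barbell, part) == pytest.approx(0.0)

    def test_two_disjoint_triangles_half(self):
        net = Network.from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
        )
        assert modularity(net, components_partition(net)) == pytest.approx(0.5)

    def test_all_singletons_closed_form(self):
        for seed in range(4):
            net = random_network(12, 0.3, seed)
            if net.n_edges == 0:
                continue
            part = Partition({n: n for n in net.nodes})
            m = net.n_edges
            want = -sum((net.degree(n) / (2 * m)) ** 2 for n in net.nodes)
            assert modularity(net, part) == pytest.approx(want, abs=1e-12)

    def test_matches_networkx_oracle(self):
        for seed in range(6):
            net = random_network(15, 0.25, seed)
            if net.n_edges == 0:
                continue
            g = net.to_networkx()
            part = components_partition(net)
            want = nx.community.modularity(g, part.communities.values())
            assert modularity(net, part) == pytest.approx(want, abs=1e-12)

    def test_edgeless_graph_undefined(self):
        net = Network.from_edges([], nodes=["a"])
        with pytest.raises(UndefinedModularityError):
            modularity(net, Partition({"a": 0}))


class TestDetectBarbell:
    def test_removes_exactly_the_bridge(self, barbell):
        trace = detect(barbell)
        assert trace.removed_edges() == [("c", "d")]
        assert trace.steps[0].kappa == pytest.approx(-2 / 3)
        assert sorted(map(len, trace.final_partition.communities.values())) == [3, 3]

    def test_side_info_protects_the_bridge(self, barbell):
        si = SideInfo.from_dict({"c": {"X"}, "d": {"X"}})
        trace = detect(barbell, si)
        assert trace.n_removed == 0
        assert trace.final_partition.n_communities == 1

    def test_use_side_info_false_ignores_labels(self, barbell):
        si = SideInfo.from_dict({"c": {"X"}, "d": {"X"}})
        trace = detect(barbell, si, DetectionConfig(use_side_info=False))
        assert trace.removed_edges() == [("c", "d")]

    def test_negative_free_graph_untouched(self, triangle):
        trace = detect(triangle)
        assert trace.n_removed == 0
        assert trace.final_partition == trace.initial_partition


class TestTraceInvariants:
    @pytest.mark.parametrize("distance_mode", ["original", "residual"])
    def test_partitions_refine_along_steps(self, distance_mode):
        net = random_network(18, 0.2, 5)
        trace = detect(net, cfg=DetectionConfig(distance_mode=distance_mode))
        prev = trace.initial_partition
        prev_k = prev.n_communities
        for step in trace.steps:
            part = step.partition
            assert part.refines(prev)
            assert part.n_communities >= prev_k
            prev, prev_k = part, part.n_communities

    def test_termination_bound(self):
        net = random_network(20, 0.25, 2)
        trace = detect(net)
        assert trace.n_removed <= net.n_edges

    def test_mm_is_argmax_earliest(self):
        net = random_network(18, 0.2, 9)
        trace = detect(net)
        qs = [trace.initial_modularity] + [s.modularity for s in trace.steps]
        best = max(qs)
        assert trace.mm_modularity == best
        assert trace.mm_step_index == qs.index(best)  # earliest on ties
        if trace.mm_step_index == 0:
            assert trace.mm_partition == trace.initial_partition
        else:
            assert trace.mm_partition == trace.steps[trace.mm_step_index - 1].partition

    def test_protected_edges_survive(self):
        net = random_network(16, 0.25, 3)
        edges = sorted(net.edges)
        si_nodes = {u for e in edges[:5] for u in e}
        si = SideInfo.from_dict({n: {"K"} for n in si_nodes})
        trace = detect(net, si)
        protected = {e for e in net.edges if is_protected(e, si)}
        assert protected.isdisjoint(trace.removed_edges())

    def test_edgeless_input(self):
        net = Network.from_edges([], nodes=["a", "b"])
        trace = detect(net)
        assert trace.n_removed == 0
        assert trace.final_partition.n_communities == 2

    def test_empty_network_raises(self):
        with pytest.raises(GraphError):
            detect(Network(nodes=frozenset(), edges=frozenset()))

    def test_component_independence(self):
        """Detection on a disjoint union equals per-component detections."""
        a = random_network(10, 0.35, 1)
        b_edges = [(u.replace("v", "w"), v.replace("v", "w"))
                   for u, v in random_network(10, 0.35, 2).edges]
        union = Network.from_edges(list(a.edges) + b_edges)
        got = set(detect(union).removed_edges())
        want_a = set(detect(a.subgraph({n for e in a.edges for n in e})).removed_edges())
        b = Network.from_edges(b_edges)
        want_b = set(detect(b).removed_edges())
        assert got == want_a | want_b


class TestIncrementalEquivalence:
    @pytest.mark.parametrize("distance_mode", ["original", "residual"])
    def test_bit_identical_traces_small(self, distance_mode):
        for seed in range(6):
            net = random_network(15, 0.25, seed + 100)
            t1 = detect(net, cfg=DetectionConfig(distance_mode=distance_mode))
            t2 = detect(
                net,
                cfg=DetectionConfig(distance_mode=distance_mode, full_recompute=True),
            )
            assert t1.removed_edges() == t2.removed_edges()
            assert [s.kappa for s in t1.steps] == [s.kappa for s in t2.steps]
            assert [s.modularity for s in t1.steps] == [s.modularity for s in t2.steps]
            assert t1.mm_step_index == t2.mm_step_index
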