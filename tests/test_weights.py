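import math

import networkx as nx
import pytest

import pollinet as pn
from pollinet.weights import RELATION_NAMES, build_essential_index

from conftest import brute_force_ecc, er_subnetwork


def subnetwork_from_edges(edges, timestamp=1) -> pn.DynamicSubnetwork:
    g = nx.Graph()
    g.add_edges_from(edges)
    return pn.DynamicSubnetwork(timestamp=timestamp, graph=g)


class TestCoEssentiality:
    def test_nonessential_endpoint_scores_zero(self):
        sub = subnetwork_from_edges([("A", "B")])
        index = build_essential_index(sub, {"A"})
        assert pn.co_essentiality(("A", "B"), index) == 0.0

    def test_symmetrized_column_sums(self):
        # essential path A-B-C: edge (A,B): A has 1 incident essential edge, B has 2
        sub = subnetwork_from_edges([("A", "B"), ("B", "C")])
        index = build_essential_index(sub, {"A", "B", "C"})
        assert pn.co_essentiality(("A", "B"), index) == pytest.approx((1 / 1 + 1 / 2) / 2)
        assert pn.co_essentiality(("B", "A"), index) == pn.co_essentiality(("A", "B"), index)

    def test_isolated_essential_edge_is_maximal(self):
        sub = subnetwork_from_edges([("A", "B")])
        index = build_essential_index(sub, {"A", "B"})
        assert pn.co_essentiality(("A", "B"), index) == 1.0


class TestSetOverlapRelations:
    def test_identical_localization(self):
        bundle = pn.AnnotationBundle(scl={"A": {"nucleus"}, "B": {"nucleus"}})
        assert pn.co_localization(("A", "B"), bundle) == 1.0

    def test_partial_localization(self):
        bundle = pn.AnnotationBundle(scl={"A": {"nucleus", "cytosol"}, "B": {"nucleus"}})
        assert pn.co_localization(("A", "B"), bundle) == 0.5

    def test_disjoint_or_missing_is_zero(self):
        bundle = pn.AnnotationBundle(scl={"A": {"nucleus"}, "B": {"vacuole"}})
        assert pn.co_localization(("A", "B"), bundle) == 0.0
        assert pn.co_localization(("A", "Z"), bundle) == 0.0

    def test_go_overlap(self):
        bundle = pn.AnnotationBundle(go={"A": {"g1", "g2", "g3"}, "B": {"g2", "g3"}})
        assert pn.co_annotation(("A", "B"), bundle) == pytest.approx(4 / 6)


class TestCoCluster:
    def test_triangle_edge_is_maximal(self):
        sub = subnetwork_from_edges([("A", "B"), ("B", "C"), ("C", "A")])
        assert pn.co_cluster(("A", "B"), sub) == 1.0

    def test_degree_one_endpoint_is_zero(self):
        sub = subnetwork_from_edges([("A", "B"), ("B", "C")])
        assert pn.co_cluster(("A", "B"), sub) == 0.0

    def test_non_edge_is_zero(self):
        sub = subnetwork_from_edges([("A", "B"), ("B", "C")])
        assert pn.co_cluster(("A", "C"), sub) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_graphs(self, seed):
        sub = er_subnetwork(n=25, p=0.25, seed=seed)
        for u, v in sub.graph.edges:
            assert pn.co_cluster((u, v), sub) == pytest.approx(
                brute_force_ecc(sub.graph, u, v)
            )


class TestWeightSubnetwork:
    def test_all_relations_maximal(self):
        # essential triangle, all same compartment and GO term: each relation
        # is at its maximum except co-essentiality (column sums are 2)
        sub = subnetwork_from_edges([("A", "B"), ("B", "C"), ("C", "A")])
        bundle = pn.AnnotationBundle(
            essential={"A", "B", "C"},
            scl={p: {"nucleus"} for p in "ABC"},
            go={p: {"g"} for p in "ABC"},
        )
        mrdpn = pn.weight_subnetwork(sub, bundle)
        d = mrdpn.graph.edges["A", "B"]
        assert d["co_localization"] == 1.0
        assert d["co_annotation"] == 1.0
        assert d["co_cluster"] == 1.0
        assert d["co_essentiality"] == pytest.approx(0.5)
        assert d["nw"] == pytest.approx(3.5 / 4)

    def test_no_annotations_leaves_pure_ecc(self):
        sub = subnetwork_from_edges([("A", "B"), ("B", "C"), ("C", "A"), ("C", "D")])
        mrdpn = pn.weight_subnetwork(sub, pn.AnnotationBundle())
        for u, v, d in mrdpn.graph.edges(data=True):
            assert d["nw"] == pytest.approx(pn.co_cluster((u, v), sub) / 4)

    def test_component_sum_example(self):
        ess, loc, ann, ecc = 0.75, 0.5, 2 / 3, 1.0
        assert (ess + loc + ann + ecc) / 4 == pytest.approx(0.7291667, abs=1e-6)

    def test_topology_preserved_and_bounds(self, noiseless_mrdpns):
        for mrdpn in noiseless_mrdpns:
            for _, _, d in mrdpn.graph.edges(data=True):
                for name in RELATION_NAMES:
                    assert 0.0 <= d[name] <= 1.0
                assert 0.0 <= d["nw"] <= 1.0
                assert d["nw"] == pytest.approx(d["multi_relation"] / 4)

    def test_relations_symmetric(self):
        sub = er_subnetwork(n=15, p=0.3, seed=3)
        nodes = sorted(sub.graph.nodes)
        bundle = pn.AnnotationBundle(
            essential=set(nodes[:8]),
            scl={p: {"a", "b"} for p in nodes[::2]},
            go={p: {"x"} for p in nodes[1::2]},
        )
        index = build_essential_index(sub, bundle.essential)
        for u, v in sub.graph.edges:
            assert pn.co_essentiality((u, v), index) == pn.co_essentiality((v, u), index)
            assert pn.co_localization((u, v), bundle) == pn.co_localization((v, u), bundle)
            assert pn.co_annotation((u, v), bundle) == pn.co_annotation((v, u), bundle)
            assert pn.co_cluster((u, v), sub) == pn.co_cluster((v, u), sub)
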