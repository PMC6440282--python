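"""The four pairwise relations and the multi-relation edge weight.

Every edge of a dynamic subnetwork is scored on four symmetric relations,
each in [0, 1]:

* co-essentiality — an edge joining two essential proteins is an "essential
  edge"; its score normalizes by the number of essential edges incident to
  each endpoint (averaged over the two orientations to keep the weight
  symmetric).  Edges with a non-essential endpoint score 0 and stay in the
  network.
* co-localization — squared subcellular-location overlap:
  |SCL_i & SCL_j|^2 / (|SCL_i| * |SCL_j|).
* co-annotation — the same form over GO term sets.
* co-cluster — the edge clustering coefficient: triangles on the edge over
  min(deg_i - 1, deg_j - 1).

Their sum (in [0, 4]) divided by the number of relations (4) is the
normalized weight NW in [0, 1] carried by the multi-relation reconstructed
dynamic PPI network (MRDPN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .dynamic import DynamicSubnetwork

N_RELATIONS = 4
RELATION_NAMES = ("co_essentiality", "co_localization", "co_annotation", "co_cluster")

__all__ = [
    "N_RELATIONS",
    "RELATION_NAMES",
    "AnnotationBundle",
    "EssentialEdgeIndex",
    "MRDPN",
    "WeightedEdge",
    "build_essential_index",
    "co_essentiality",
    "co_localization",
    "co_annotation",
    "co_cluster",
    "weight_subnetwork",
]


@dataclass
class AnnotationBundle:
    """Essentiality, localization and GO annotation lookup tables.

    A protein missing from a source contributes the empty set (hence 0 to the
    corresponding relation).
    """

    essential: set[str] = field(default_factory=set)
    scl: dict[str, set[str]] = field(default_factory=dict)
    go: dict[str, set[str]] = field(default_factory=dict)

    def scl_of(self, protein: str) -> set[str]:
        return self.scl.get(protein, set())

    def go_of(self, protein: str) -> set[str]:
        return self.go.get(protein, set())


@dataclass
class EssentialEdgeIndex:
    """Essential edges of one subnetwork and per-protein incident counts."""

    essential_edges: set[tuple[str, str]] = field(default_factory=set)
    column_sum: dict[str, int] = field(default_factory=dict)


def build_essential_index(subnetwork: DynamicSubnetwork, essential: set[str]) -> EssentialEdgeIndex:
    """Index the essential edges (both endpoints essential) of one subnetwork.

    Counts are taken over the edges present at this timestamp, not over the
    static network.
    """
    index = EssentialEdgeIndex()
    for u, v in subnetwork.graph.edges:
        if u in essential and v in essential:
            edge = (u, v) if u <= v else (v, u)
            index.essential_edges.add(edge)
            index.column_sum[u] = index.column_sum.get(u, 0) + 1
            index.column_sum[v] = index.column_sum.get(v, 0) + 1
    return index


def co_essentiality(pair: tuple[str, str], index: EssentialEdgeIndex) -> float:
    """Symmetrized essential-edge weight; 0 for uncertain/nonessential edges."""
    u, v = pair
    edge = (u, v) if u <= v else (v, u)
    if edge not in index.essential_edges:
        return 0.0
    # column sums are >= 1 for both endpoints of an essential edge
    return 0.5 * (1.0 / index.column_sum[u] + 1.0 / index.column_sum[v])


def _set_overlap_score(a: set[str], b: set[str]) -> float:
    if not a or not b:
        return 0.0
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def co_localization(pair: tuple[str, str], bundle: AnnotationBundle) -> float:
    u, v = pair
    return _set_overlap_score(bundle.scl_of(u), bundle.scl_of(v))


def co_annotation(pair: tuple[str, str], bundle: AnnotationBundle) -> float:
    u, v = pair
    return _set_overlap_score(bundle.go_of(u), bundle.go_of(v))


def co_cluster(pair: tuple[str, str], subnetwork: DynamicSubnetwork | nx.Graph) -> float:
    """Edge clustering coefficient of a pair in a subnetwork.

    Z_ij / min(deg_i - 1, deg_j - 1) with Z_ij the number of triangles on the
    edge; 0 for non-edges, absent nodes, or a degenerate denominator.
    """
    g = subnetwork.graph if isinstance(subnetwork, DynamicSubnetwork) else subnetwork
    u, v = pair
    if not g.has_edge(u, v):
        return 0.0
    denom = min(g.degree[u], g.degree[v]) - 1
    if denom <= 0:
        return 0.0
    triangles = len(set(g.adj[u]) & set(g.adj[v]))
    return triangles / denom


@dataclass
class WeightedEdge:
    """One edge of an MRDPN with its four relation values and normalized weight."""

    endpoints: tuple[str, str]
    co_essentiality: float
    co_localization: float
    co_annotation: float
    co_cluster: float
    multi_relation: float
    nw: float


@dataclass
class MRDPN:
    """Multi-relation reconstructed dynamic PPI network at one timestamp.

    Same topology as the source subnetwork; each edge carries the four
    relations, their sum `multi_relation` and `nw = multi_relation / 4`.
    """

    timestamp: int
    graph: nx.Graph = field(default_factory=nx.Graph)

    def nw(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["nw"]

    @property
    def weighted_edges(self) -> list[WeightedEdge]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            endpoints = (u, v) if u <= v else (v, u)
            out.append(
                WeightedEdge(
                    endpoints=endpoints,
                    co_essentiality=d["co_essentiality"],
                    co_localization=d["co_localization"],
                    co_annotation=d["co_annotation"],
                    co_cluster=d["co_cluster"],
                    multi_relation=d["multi_relation"],
                    nw=d["nw"],
                )
            )
        return out


def weight_subnetwork(subnetwork: DynamicSubnetwork, bundle: AnnotationBundle) -> MRDPN:
    """Annotate every edge of a subnetwork with the four relations and NW."""
    index = build_essential_index(subnetwork, bundle.essential)
    g = nx.Graph()
    g.add_nodes_from(subnetwork.graph.nodes)
    for u, v in subnetwork.graph.edges:
        pair = (u, v)
        ess = co_essentiality(pair, index)
        loc = co_localization(pair, bundle)
        ann = co_annotation(pair, bundle)
        ecc = co_cluster(pair, subnetwork)
        multi = ess + loc + ann + ecc
        g.add_edge(
            u,
            v,
            co_essentiality=ess,
            co_localization=loc,
            co_annotation=ann,
            co_cluster=ecc,
            multi_relation=multi,
            nw=multi / N_RELATIONS,
        )
    return MRDPN(timestamp=subnetwork.timestamp, graph=g)
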