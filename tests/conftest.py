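import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

import pollinet as pn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def noiseless_dataset() -> pn.SyntheticDataset:
    """Clean planted benchmark: clique cores, no background edges, full annotations."""
    return pn.generate_dataset(pn.PlantedModel(rng_seed=11))


@pytest.fixture(scope="session")
def noisy_dataset() -> pn.SyntheticDataset:
    """Moderate-noise benchmark: spurious edges and diluted annotations."""
    return pn.generate_dataset(
        pn.PlantedModel(background_edge_prob=0.02, annotation_overlap=0.5, rng_seed=11)
    )


@pytest.fixture(scope="session")
def noiseless_mrdpns(noiseless_dataset) -> list[pn.MRDPN]:
    ds = noiseless_dataset
    profiles = pn.make_profiles(ds.expression)
    subnets = pn.build_subnetworks(ds.network, profiles)
    return [pn.weight_subnetwork(s, ds.bundle) for s in subnets]


def er_subnetwork(n: int, p: float, seed: int, timestamp: int = 1) -> pn.DynamicSubnetwork:
    """Seeded Erdos-Renyi graph wrapped as a dynamic subnetwork."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    g = nx.relabel_nodes(g, {i: f"P{i:02d}" for i in g.nodes})
    return pn.DynamicSubnetwork(timestamp=timestamp, graph=g)


def uniform_mrdpn(graph: nx.Graph, nw: float, timestamp: int = 1) -> pn.MRDPN:
    """Wrap a topology as an MRDPN with one uniform edge weight."""
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    for u, v in graph.edges:
        g.add_edge(
            u, v,
            co_essentiality=0.0, co_localization=0.0, co_annotation=0.0,
            co_cluster=0.0, multi_relation=4 * nw, nw=nw,
        )
    return pn.MRDPN(timestamp=timestamp, graph=g)


def brute_force_ecc(g: nx.Graph, u, v) -> float:
    """Independent edge-clustering-coefficient oracle by triple enumeration."""
    if not g.has_edge(u, v):
        return 0.0
    triangles = sum(1 for w in g.nodes if w not in (u, v) and g.has_edge(u, w) and g.has_edge(v, w))
    denom = min(g.degree[u], g.degree[v]) - 1
    return triangles / denom if denom > 0 else 0.0


def brute_force_priority(g: nx.Graph, pollen, members) -> float:
    return sum(brute_force_ecc(g, pollen, u) for u in members)
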