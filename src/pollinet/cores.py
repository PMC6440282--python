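"""Mining protein-complex cores by seeded density extension.

Seeds are proteins whose weighted degree (sum of incident NW values) strictly
exceeds the network average, taken in descending order.  Each seed grows a
core over its direct neighbors: a neighbor is admitted iff the post-addition
density

    Density(CS) = 2 * sum of NW over internal edges / (|CS| * (|CS| - 1))

strictly exceeds the density threshold DT.  Admitted nodes are labeled and
never enter another core, so the cores of one subnetwork are disjoint.  The
whole procedure is deterministic: ties in degree and in neighbor weight are
broken lexicographically by protein ID.
"""

from __future__ import annotations

from dataclasses import dataclass

from .weights import MRDPN

DEFAULT_DT = 0.25

__all__ = ["DEFAULT_DT", "MiningConfig", "CoreSet", "weighted_degree", "candidate_cores", "extend_seed", "find_cores", "core_density"]


@dataclass
class MiningConfig:
    """Core-mining parameters; dt is the density threshold in (0, 1)."""

    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if not 0.0 < self.dt < 1.0:
            raise ValueError(f"density threshold dt must be in (0, 1), got {self.dt}")


@dataclass(frozen=True)
class CoreSet:
    """A mined complex core: members, internal density, originating seed."""

    members: frozenset[str]
    density: float
    seed: str


def weighted_degree(protein: str, network: MRDPN) -> float:
    """Sum of NW over the edges incident to `protein`."""
    g = network.graph
    if protein not in g:
        raise KeyError(f"protein {protein!r} not in network")
    return sum(g.edges[protein, nbr]["nw"] for nbr in g.adj[protein])


def candidate_cores(network: MRDPN) -> list[str]:
    """Proteins with weighted degree strictly above the network mean, descending.

    Ties are broken lexicographically by protein ID.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        return []
    wd = {v: weighted_degree(v, network) for v in g.nodes}
    mean = sum(wd.values()) / len(wd)
    above = [v for v, w in wd.items() if w > mean]
    return sorted(above, key=lambda v: (-wd[v], v))


def core_density(members, network: MRDPN) -> float:
    """Density of a member set under the weighted-density formula (needs >= 2 members)."""
    members = list(members)
    k = len(members)
    if k < 2:
        raise ValueError("density undefined for fewer than 2 members")
    g = network.graph
    total = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            if g.has_edge(members[i], members[j]):
                total += g.edges[members[i], members[j]]["nw"]
    return 2.0 * total / (k * (k - 1))


def extend_seed(seed: str, network: MRDPN, config: MiningConfig, used: set[str]) -> CoreSet | None:
    """Grow a core from one seed; returns None if it never reaches 2 members.

    The seed's unused neighbors are scanned once, in descending order of NW to
    the seed (lexicographic ties); each is admitted iff the density after
    adding it exceeds dt.
    """
    g = network.graph
    neighbors = [n for n in g.adj[seed] if n not in used]
    neighbors.sort(key=lambda n: (-g.edges[seed, n]["nw"], n))
    members: list[str] = [seed]
    internal_sum = 0.0
    for cand in neighbors:
        gain = sum(
            g.edges[cand, m]["nw"] for m in members if g.has_edge(cand, m)
        )
        k = len(members) + 1
        density = 2.0 * (internal_sum + gain) / (k * (k - 1))
        if density > config.dt:
            members.append(cand)
            internal_sum += gain
    if len(members) < 2:
        return None
    k = len(members)
    return CoreSet(
        members=frozenset(members),
        density=2.0 * internal_sum / (k * (k - 1)),
        seed=seed,
    )


def find_cores(network: MRDPN, config: MiningConfig | None = None) -> list[CoreSet]:
    """Mine all cores of one subnetwork; cores are pairwise disjoint."""
    config = config or MiningConfig()
    used: set[str] = set()
    cores: list[CoreSet] = []
    for seed in candidate_cores(network):
        if seed in used:
            continue
        core = extend_seed(seed, network, config, used)
        if core is not None:
            cores.append(core)
            used |= core.members
    return cores
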