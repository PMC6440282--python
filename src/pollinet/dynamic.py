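"""Per-protein activity thresholds and dynamic PPI subnetwork construction.

A protein is "active" at a timestamp when its (cycle-averaged) expression
value reaches its three-sigma activity threshold

    Active_Th(v) = mu(v) + 3 * sigma(v) * (1 - F(v)),   F(v) = 1 / (1 + sigma(v)^2)

where mu and sigma are the mean and population standard deviation of the
gene's expression values over the full time course.  F down-weights the
three-sigma margin for noisy genes: a flat profile (sigma = 0) has F = 1 and
threshold exactly mu, while a highly variable profile approaches the plain
mu + 3 sigma rule.  The static network is then split into one subnetwork per
timestamp: an interaction is present at time t iff both endpoints are active
at t and the edge exists in the static network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .io_formats import StaticNetwork

logger = logging.getLogger(__name__)

N_TIMESTAMPS = 12

__all__ = [
    "N_TIMESTAMPS",
    "ExpressionProfile",
    "DynamicSubnetwork",
    "activity_threshold",
    "cycle_average",
    "make_profile",
    "make_profiles",
    "build_subnetworks",
]


@dataclass
class ExpressionProfile:
    """Cycle-averaged time course of one gene plus its activity threshold.

    mu and sigma are computed over the raw (all-cycles) values; activity at a
    timestamp is judged on the cycle-averaged value.
    """

    gene: str
    per_timestamp: list[float]
    mu: float
    sigma: float
    weight_f: float
    active_th: float

    def is_active(self, timestamp: int) -> bool:
        """True iff the cycle-averaged value at `timestamp` (1-based) reaches the threshold."""
        return self.per_timestamp[timestamp - 1] >= self.active_th


@dataclass
class DynamicSubnetwork:
    """The subgraph induced by proteins active at one timestamp."""

    timestamp: int
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def active_nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(u, v) if u <= v else (v, u) for u, v in self.graph.edges}

    def degree(self, node: str) -> int:
        return self.graph.degree[node]


def activity_threshold(values) -> tuple[float, float, float, float]:
    """Return (mu, sigma, F, Active_Th) for one gene's expression values.

    sigma is the population (divide-by-n) standard deviation.  When sigma = 0
    the threshold collapses to mu.
    """
    values = list(values)
    if not values:
        raise ValueError("activity_threshold: empty expression sequence")
    if not all(math.isfinite(v) for v in values):
        raise ValueError("activity_threshold: non-finite expression value")
    n = len(values)
    mu = sum(values) / n
    var = sum((v - mu) ** 2 for v in values) / n
    sigma = math.sqrt(var)
    weight_f = 1.0 / (1.0 + var)
    active_th = mu + 3.0 * sigma * (1.0 - weight_f)
    return mu, sigma, weight_f, active_th


def cycle_average(values, cycles: int) -> list[float]:
    """Average a cycles x 12 sequence down to one value per timestamp."""
    values = list(values)
    if cycles < 1 or len(values) != cycles * N_TIMESTAMPS:
        raise ValueError(
            f"cycle_average: expected {cycles}x{N_TIMESTAMPS} = {cycles * N_TIMESTAMPS} values, got {len(values)}"
        )
    return [
        sum(values[c * N_TIMESTAMPS + t] for c in range(cycles)) / cycles
        for t in range(N_TIMESTAMPS)
    ]


def make_profile(gene: str, raw_values, cycles: int = 3) -> ExpressionProfile:
    """Build an ExpressionProfile: threshold from the raw values, activity on cycle averages."""
    mu, sigma, weight_f, active_th = activity_threshold(raw_values)
    return ExpressionProfile(
        gene=gene,
        per_timestamp=cycle_average(raw_values, cycles),
        mu=mu,
        sigma=sigma,
        weight_f=weight_f,
        active_th=active_th,
    )


def make_profiles(expression: dict[str, list[float]], cycles: int = 3) -> dict[str, ExpressionProfile]:
    return {gene: make_profile(gene, vals, cycles) for gene, vals in expression.items()}


def build_subnetworks(
    network: StaticNetwork, profiles: dict[str, ExpressionProfile]
) -> list[DynamicSubnetwork]:
    """Split the static network into 12 dynamic subnetworks.

    Proteins with no expression record are treated as never active and are
    excluded from every subnetwork (their count is logged).
    """
    missing = len(network.nodes - profiles.keys())
    if missing:
        logger.info("build_subnetworks: %d network proteins lack expression data", missing)
    subnets = []
    for t in range(1, N_TIMESTAMPS + 1):
        active = {
            v for v in network.nodes if v in profiles and profiles[v].is_active(t)
        }
        g = nx.Graph()
        g.add_nodes_from(sorted(active))
        g.add_edges_from(
            (u, v) for u, v in network.edges if u in active and v in active
        )
        subnets.append(DynamicSubnetwork(timestamp=t, graph=g))
    return subnets
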