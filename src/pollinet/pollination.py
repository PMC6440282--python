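"""Attaching peripheral proteins to cores by discrete flower pollination.

Cores play the role of flowering plants and the remaining subnetwork
proteins are pollen.  A pollen's position is a core index; its affinity for
a core is the pollination priority

    priority(pollen, CS) = sum over u in CS of co_cluster(pollen, u)

computed on the subnetwork topology (non-adjacent pairs contribute 0).  Each
iteration a pollen stays on its core if its priority there exceeds the
threshold Thr, and otherwise jumps to a uniformly random core.  Once a
pollen lands on a satisfying core it never moves again, so the walk is a
random search over core indices that terminates when every pollen is stable
or the iteration budget is exhausted.  Pollen that satisfy no core are
discarded.  The per-timestamp complexes (core plus attachments) are then
pooled over the twelve subnetworks, deduplicated, and greedily filtered so
that no two retained complexes overlap at or above the overlap-score cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cores import CoreSet
from .dynamic import DynamicSubnetwork
from .evaluation import overlapping_score
from .io_formats import ComplexCatalog
from .weights import MRDPN, co_cluster

logger = logging.getLogger(__name__)

__all__ = [
    "IFPAConfig",
    "PollenState",
    "PredictedComplex",
    "pollination_priority",
    "initialize_pollen",
    "update_positions",
    "run_ifpa",
    "merge_and_filter",
]


@dataclass
class IFPAConfig:
    """Attachment-phase parameters.

    thr: pollination-priority threshold for keeping/attaching (default 0.2).
    max_iter: iteration budget for the random search.
    rng_seed: seed for the single generator driving initialization and jumps.
    overlap_filter: overlap-score cutoff for cross-timestamp filtering.
    """

    thr: float = 0.2
    max_iter: int = 100
    rng_seed: int = 0
    overlap_filter: float = 0.8

    def __post_init__(self) -> None:
        if self.thr < 0:
            raise ValueError("thr must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 < self.overlap_filter <= 1.0:
            raise ValueError("overlap_filter must be in (0, 1]")


@dataclass
class PollenState:
    """Assignments of pollen proteins to core indices during the search.

    priority holds each pollen's priority at its current core; the full
    pollen x core priority table is cached because core membership and
    subnetwork topology are fixed during a run.
    """

    assignment: dict[str, int] = field(default_factory=dict)
    priority: dict[str, float] = field(default_factory=dict)
    iteration: int = 0
    priority_table: dict[str, list[float]] = field(default_factory=dict)


@dataclass(frozen=True)
class PredictedComplex:
    """A core plus its attached periphery from one subnetwork."""

    core: frozenset[str]
    attachments: frozenset[str]
    source_timestamp: int = 0

    @property
    def members(self) -> frozenset[str]:
        return self.core | self.attachments


def pollination_priority(
    pollen: str,
    core: CoreSet | Iterable[str],
    subnetwork: DynamicSubnetwork | MRDPN,
) -> float:
    """Sum of edge clustering coefficients between a pollen and all core members."""
    members = core.members if isinstance(core, CoreSet) else core
    g = subnetwork.graph
    return sum(co_cluster((pollen, u), g) for u in members)


def initialize_pollen(
    cores: Sequence[CoreSet],
    network: MRDPN,
    config: IFPAConfig,
    rng: np.random.Generator | None = None,
) -> PollenState:
    """Assign every non-core protein a uniformly random core index."""
    state = PollenState()
    if not cores:
        logger.warning("initialize_pollen: no cores at timestamp %d", network.timestamp)
        return state
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    in_core = set().union(*(c.members for c in cores))
    pollen = sorted(set(network.graph.nodes) - in_core)
    for p in pollen:
        state.priority_table[p] = [
            pollination_priority(p, c, network) for c in cores
        ]
    for p in pollen:
        idx = int(rng.integers(len(cores)))
        state.assignment[p] = idx
        state.priority[p] = state.priority_table[p][idx]
    return state


def update_positions(
    state: PollenState,
    cores: Sequence[CoreSet],
    network: MRDPN,
    config: IFPAConfig,
    rng: np.random.Generator | None = None,
) -> PollenState:
    """One pollination iteration: satisfied pollen stay, the rest jump randomly."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    for p in sorted(state.assignment):
        if state.priority[p] > config.thr:
            continue
        idx = int(rng.integers(len(cores)))
        state.assignment[p] = idx
        state.priority[p] = state.priority_table[p][idx]
    state.iteration += 1
    return state


def run_ifpa(
    cores: Sequence[CoreSet],
    network: MRDPN,
    config: IFPAConfig | None = None,
) -> list[PredictedComplex]:
    """Attach pollen to cores; one complex per core (possibly with no attachments).

    Iterates until every pollen sits on a core where its priority exceeds thr,
    or max_iter is reached.  Pollen whose final priority never exceeds thr are
    discarded.
    """
    config = config or IFPAConfig()
    if not cores:
        return []
    rng = np.random.default_rng(config.rng_seed)
    state = initialize_pollen(cores, network, config, rng)
    for _ in range(config.max_iter):
        if all(pr > config.thr for pr in state.priority.values()):
            break
        update_positions(state, cores, network, config, rng)
    attached: dict[int, set[str]] = {i: set() for i in range(len(cores))}
    for p, idx in state.assignment.items():
        if state.priority[p] > config.thr:
            attached[idx].add(p)
    return [
        PredictedComplex(
            core=core.members,
            attachments=frozenset(attached[i]),
            source_timestamp=network.timestamp,
        )
        for i, core in enumerate(cores)
    ]


def merge_and_filter(
    per_timestamp: Iterable[Sequence[PredictedComplex]],
    config: IFPAConfig | None = None,
) -> ComplexCatalog:
    """Pool complexes over timestamps, drop duplicates, filter heavy overlaps.

    Complexes are ranked by size descending (lexicographic ties) and kept iff
    their overlap score with every already-kept complex is below
    overlap_filter, so the retained catalog has pairwise OS < overlap_filter.
    """
    config = config or IFPAConfig()
    seen: set[frozenset[str]] = set()
    pool: list[frozenset[str]] = []
    for complexes in per_timestamp:
        for c in complexes:
            members = c.members
            if len(members) < 2 or members in seen:
                continue
            seen.add(members)
            pool.append(members)
    pool.sort(key=lambda m: (-len(m), tuple(sorted(m))))
    kept: list[frozenset[str]] = []
    for members in pool:
        if all(overlapping_score(members, k) < config.overlap_filter for k in kept):
            kept.append(members)
    return ComplexCatalog(complexes=kept, name="predicted")
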