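"""Readers and writers for the plain-text formats the pipeline touches.

All files are whitespace/tab-separated text.  Lines starting with ``#`` are
comments and blank lines are skipped everywhere.  Protein identifiers are
case-sensitive opaque strings; no identifier mapping or aliasing is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "StaticNetwork",
    "ComplexCatalog",
    "ParseError",
    "read_edgelist",
    "read_expression",
    "read_annotations",
    "read_complexes",
    "write_complexes",
    "write_edgelist",
    "write_weighted_tsv",
    "write_graphml",
]


class ParseError(ValueError):
    """A file did not conform to its documented dialect."""


def _canonical(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def _data_lines(path: Path) -> Iterator[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


@dataclass
class StaticNetwork:
    """An undirected protein-protein interaction network.

    Edges are stored once as lexicographically ordered pairs; self-loops are
    never present.
    """

    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            return
        self.nodes.add(u)
        self.nodes.add(v)
        self.edges.add(_canonical(u, v))

    def has_edge(self, u: str, v: str) -> bool:
        return _canonical(u, v) in self.edges

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class ComplexCatalog:
    """An ordered collection of protein complexes (protein-ID sets)."""

    complexes: list[frozenset[str]] = field(default_factory=list)
    name: str = ""

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.complexes)

    def member_sets(self) -> set[frozenset[str]]:
        return set(self.complexes)


def read_edgelist(path: str | Path) -> StaticNetwork:
    """Read a two-column edge list into a deduplicated undirected network.

    Extra columns (e.g. confidence scores) are ignored with a logged note.
    Self-loops and duplicate edges are dropped, with counts logged.
    """
    path = Path(path)
    net = StaticNetwork()
    self_loops = duplicates = 0
    extra_cols_seen = False
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) < 2:
            raise ParseError(f"{path}:{lineno}: expected at least 2 columns, got {len(tokens)}")
        if len(tokens) > 2:
            extra_cols_seen = True
        u, v = tokens[0], tokens[1]
        if u == v:
            self_loops += 1
            continue
        edge = _canonical(u, v)
        if edge in net.edges:
            duplicates += 1
            continue
        net.nodes.update(edge)
        net.edges.add(edge)
    if extra_cols_seen:
        logger.info("%s: extra columns beyond the first two were ignored", path)
    if self_loops or duplicates:
        logger.info("%s: dropped %d self-loops and %d duplicate edges", path, self_loops, duplicates)
    return net


def read_expression(path: str | Path, cycles: int = 3, timestamps: int = 12) -> dict[str, list[float]]:
    """Read a gene-expression matrix: header row, then gene + cycles*timestamps values.

    Returns a mapping gene ID -> sequence of ``cycles * timestamps`` floats in
    file order.  A gene appearing twice keeps its last row (warning logged).
    """
    path = Path(path)
    expected = cycles * timestamps
    out: dict[str, list[float]] = {}
    lines = _data_lines(path)
    try:
        next(lines)  # header row of sample labels
    except StopIteration:
        return out
    for lineno, line in lines:
        tokens = line.split()
        gene = tokens[0]
        cells = tokens[1:]
        if len(cells) != expected:
            raise ParseError(
                f"{path}:{lineno}: gene {gene!r} has {len(cells)} values, expected {expected}"
            )
        try:
            values = [float(c) for c in cells]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric cell for gene {gene!r}: {exc}") from None
        if gene in out:
            logger.warning("%s:%d: duplicate gene %r, last occurrence wins", path, lineno, gene)
        out[gene] = values
    return out


def read_annotations(path: str | Path, mode: str):
    """Read an annotation table.

    mode='localization' or 'go': two-column TSV (protein, term) -> protein ->
    deduplicated term set.  mode='essential': one ID per line -> a set of IDs.
    """
    path = Path(path)
    if mode == "essential":
        ids: set[str] = set()
        for _, line in _data_lines(path):
            ids.add(line.split()[0])
        return ids
    if mode not in ("localization", "go"):
        raise ValueError(f"unrecognized annotation mode {mode!r}")
    table: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns (protein, term)")
        table.setdefault(tokens[0], set()).add(tokens[1])
    return table


def read_complexes(path: str | Path, name: str = "") -> ComplexCatalog:
    """Read a catalog: one complex per line, members whitespace separated.

    Singleton lines are dropped with a warning; duplicate complexes (identical
    member sets) are removed, keeping first occurrence.
    """
    path = Path(path)
    catalog = ComplexCatalog(name=name or path.stem)
    seen: set[frozenset[str]] = set()
    singletons = 0
    for _, line in _data_lines(path):
        members = frozenset(line.split())
        if len(members) < 2:
            singletons += 1
            continue
        if members in seen:
            continue
        seen.add(members)
        catalog.complexes.append(members)
    if singletons:
        logger.warning("%s: dropped %d singleton complexes", path, singletons)
    return catalog


def write_complexes(catalog: ComplexCatalog, path: str | Path) -> None:
    """Write a catalog, one complex per line, members sorted for stable output."""
    path = Path(path)
    with open(path, "w") as fh:
        for members in catalog.complexes:
            fh.write("\t".join(sorted(members)) + "\n")


def write_edgelist(network: StaticNetwork | Iterable[tuple[str, str]], path: str | Path) -> None:
    edges = network.edges if isinstance(network, StaticNetwork) else network
    with open(path, "w") as fh:
        for u, v in sorted(edges):
            fh.write(f"{u}\t{v}\n")


def write_weighted_tsv(mrdpn, path: str | Path) -> None:
    """Export a weighted network as TSV: node1, node2, NW, four relation columns."""
    g = mrdpn.graph
    cols = ("co_essentiality", "co_localization", "co_annotation", "co_cluster")
    with open(path, "w") as fh:
        fh.write("#node1\tnode2\tnw\t" + "\t".join(cols) + "\n")
        for u, v in sorted(_canonical(u, v) for u, v in g.edges):
            d = g.edges[u, v]
            vals = "\t".join(f"{d[c]:.6g}" for c in cols)
            fh.write(f"{u}\t{v}\t{d['nw']:.6g}\t{vals}\n")


def write_graphml(mrdpn, path: str | Path) -> None:
    nx.write_graphml(mrdpn.graph, str(path))
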