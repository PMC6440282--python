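"""Synthetic benchmark generator with planted core-attachment complexes.

Produces every input the pipeline consumes — static network, three-cycle
expression matrix, localization/GO tables, essential-protein list and a
ground-truth catalog — from a single seed.  Each planted complex is a dense
core (edge probability `intra_core_edge_prob`, 1.0 = clique) plus
`attachments_per_complex` peripheral proteins, each wired to at least two
core members so that its edge clustering coefficients, and hence its
pollination priority, are nonzero by construction.  Complexes are assigned
to timestamps round-robin and their member genes are expressed high exactly
at that timestamp; background genes carry high-variance noise whose maximum
stays below their three-sigma activity threshold, so they are never active.
A background Erdos-Renyi layer adds spurious edges between pairs that do not
share a complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from .dynamic import N_TIMESTAMPS, activity_threshold, cycle_average
from .io_formats import ComplexCatalog, StaticNetwork, write_edgelist
from .weights import AnnotationBundle

# The eleven compartment labels used for synthetic localization terms.
LOCALIZATION_TERMS = (
    "Cytoskeleton", "Golgi_apparatus", "Peroxisome", "Nucleus",
    "Extracellular_space", "Vacuole", "Cytosol", "Endosome",
    "Mitochondrion", "Plasma_membrane", "Endoplasmic_reticulum",
)

__all__ = [
    "PlantedModel",
    "PlantedComplex",
    "SyntheticDataset",
    "generate_dataset",
    "generate_network",
    "generate_expression",
    "generate_annotations",
    "write_dataset",
    "DATASET_FILENAMES",
]

DATASET_FILENAMES = {
    "network": "network.tsv",
    "expression": "expression.tsv",
    "localization": "localization.tsv",
    "go": "go.tsv",
    "essential": "essential.txt",
    "reference": "complexes_ref.txt",
    "manifest": "manifest.json",
}


@dataclass(frozen=True)
class PlantedModel:
    """Parameters of the planted core-attachment benchmark.

    Defaults describe a clean, fully annotated instance: clique cores of
    3-6 proteins, two attachments per complex, no background edges, and all
    members annotated with their complex's localization/GO term.  Noise is
    introduced by raising background_edge_prob and lowering
    annotation_overlap.
    """

    n_complexes: int = 10
    core_size_range: tuple[int, int] = (3, 6)
    attachments_per_complex: int = 2
    background_nodes: int = 50
    intra_core_edge_prob: float = 1.0
    background_edge_prob: float = 0.0
    active_expression_level: float = 10.0
    inactive_level: float = 0.5
    annotation_overlap: float = 1.0
    essential_fraction: float = 1.0
    cycles: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.intra_core_edge_prob, self.background_edge_prob,
                  self.annotation_overlap, self.essential_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.core_size_range[0] < 3 or self.core_size_range[0] > self.core_size_range[1]:
            raise ValueError(f"infeasible core_size_range {self.core_size_range}")
        if self.n_complexes < 1 or self.background_nodes < 0 or self.cycles < 1:
            raise ValueError("infeasible model sizes")


@dataclass(frozen=True)
class PlantedComplex:
    """Ground truth for one planted complex."""

    index: int
    core: frozenset[str]
    attachments: frozenset[str]
    timestamp: int

    @property
    def members(self) -> frozenset[str]:
        return self.core | self.attachments


@dataclass
class SyntheticDataset:
    """A fully generated benchmark instance."""

    model: PlantedModel
    network: StaticNetwork
    truth: ComplexCatalog
    planted: list[PlantedComplex]
    expression: dict[str, list[float]]
    bundle: AnnotationBundle
    localization_rows: list[tuple[str, str]] = field(default_factory=list)
    go_rows: list[tuple[str, str]] = field(default_factory=list)


def _plant_complexes(model: PlantedModel, rng: np.random.Generator) -> list[PlantedComplex]:
    lo, hi = model.core_size_range
    planted = []
    for ci in range(model.n_complexes):
        size = int(rng.integers(lo, hi + 1))
        core = frozenset(f"C{ci:02d}_CORE{k:02d}" for k in range(size))
        atts = frozenset(
            f"C{ci:02d}_ATT{k:02d}" for k in range(model.attachments_per_complex)
        )
        planted.append(
            PlantedComplex(
                index=ci, core=core, attachments=atts,
                timestamp=(ci % N_TIMESTAMPS) + 1,
            )
        )
    return planted


def _build_network(
    model: PlantedModel, planted: list[PlantedComplex], rng: np.random.Generator
) -> StaticNetwork:
    net = StaticNetwork()
    complex_of: dict[str, int] = {}
    for pc in planted:
        core = sorted(pc.core)
        for v in pc.members:
            net.nodes.add(v)
            complex_of[v] = pc.index
        # dense core: every pair with prob intra_core_edge_prob, but keep the
        # core connected by always wiring a spanning path first
        for i in range(1, len(core)):
            net.add_edge(core[i - 1], core[i])
        for i in range(len(core)):
            for j in range(i + 1, len(core)):
                if rng.random() < model.intra_core_edge_prob:
                    net.add_edge(core[i], core[j])
        # each attachment touches >= 2 core members so its triangle counts
        # (hence pollination priority) are nonzero when the core is dense
        for att in sorted(pc.attachments):
            n_links = min(len(core), 2 + int(rng.integers(0, 2)))
            for u in rng.choice(core, size=n_links, replace=False):
                net.add_edge(att, str(u))
    for b in range(model.background_nodes):
        net.nodes.add(f"BG{b:03d}")
    # spurious background layer over pairs that do not share a complex
    if model.background_edge_prob > 0:
        nodes = sorted(net.nodes)
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                u, v = nodes[i], nodes[j]
                if complex_of.get(u, -1) == complex_of.get(v, -2):
                    continue
                if rng.random() < model.background_edge_prob:
                    net.add_edge(u, v)
    return net


def _build_expression(
    model: PlantedModel,
    network: StaticNetwork,
    planted: list[PlantedComplex],
    rng: np.random.Generator,
) -> dict[str, list[float]]:
    n_cols = model.cycles * N_TIMESTAMPS
    expression: dict[str, list[float]] = {}
    member_ts = {v: pc.timestamp for pc in planted for v in pc.members}
    for gene in sorted(network.nodes):
        if gene in member_ts:
            t = member_ts[gene]
            vals = []
            for _ in range(model.cycles):
                for tt in range(1, N_TIMESTAMPS + 1):
                    if tt == t:
                        vals.append(model.active_expression_level)
                    else:
                        vals.append(model.inactive_level + 0.1 * rng.random())
        else:
            # high-variance noise keeps sigma large, F small and the
            # three-sigma threshold above every cycle-averaged value
            vals = list(rng.uniform(0.0, model.active_expression_level, size=n_cols))
        expression[gene] = vals
    _check_activity(model, expression, member_ts)
    return expression


def _check_activity(
    model: PlantedModel,
    expression: dict[str, list[float]],
    member_ts: dict[str, int],
) -> None:
    """Verify the planted activity pattern against the three-sigma rule."""
    for gene, vals in expression.items():
        _, _, _, th = activity_threshold(vals)
        averaged = cycle_average(vals, model.cycles)
        active = {t + 1 for t, v in enumerate(averaged) if v >= th}
        want = {member_ts[gene]} if gene in member_ts else set()
        if active != want:
            raise RuntimeError(
                f"expression calibration failed for {gene}: active at {sorted(active)}, "
                f"wanted {sorted(want)}; adjust expression levels"
            )


def _build_annotations(
    model: PlantedModel, planted: list[PlantedComplex], rng: np.random.Generator
) -> tuple[AnnotationBundle, list[tuple[str, str]], list[tuple[str, str]]]:
    bundle = AnnotationBundle()
    loc_rows: list[tuple[str, str]] = []
    go_rows: list[tuple[str, str]] = []
    for pc in planted:
        loc_term = LOCALIZATION_TERMS[pc.index % len(LOCALIZATION_TERMS)]
        go_term = f"GO:SYN{pc.index:04d}"
        for v in sorted(pc.members):
            shared = rng.random() < model.annotation_overlap
            loc = loc_term if shared else f"LOC_private_{v}"
            bundle.scl.setdefault(v, set()).add(loc)
            loc_rows.append((v, loc))
            shared_go = rng.random() < model.annotation_overlap
            go = go_term if shared_go else f"GO:PRIV_{v}"
            bundle.go.setdefault(v, set()).add(go)
            go_rows.append((v, go))
        for v in sorted(pc.core):
            if rng.random() < model.essential_fraction:
                bundle.essential.add(v)
    return bundle, loc_rows, go_rows


def generate_dataset(model: PlantedModel) -> SyntheticDataset:
    """Generate the complete benchmark instance for one model (one seed)."""
    rng = np.random.default_rng(model.rng_seed)
    planted = _plant_complexes(model, rng)
    network = _build_network(model, planted, rng)
    expression = _build_expression(model, network, planted, rng)
    bundle, loc_rows, go_rows = _build_annotations(model, planted, rng)
    truth = ComplexCatalog(
        complexes=[pc.members for pc in planted], name="ground_truth"
    )
    return SyntheticDataset(
        model=model, network=network, truth=truth, planted=planted,
        expression=expression, bundle=bundle,
        localization_rows=loc_rows, go_rows=go_rows,
    )


def generate_network(model: PlantedModel) -> tuple[StaticNetwork, ComplexCatalog]:
    ds = generate_dataset(model)
    return ds.network, ds.truth


def generate_expression(model: PlantedModel) -> dict[str, list[float]]:
    return generate_dataset(model).expression


def generate_annotations(model: PlantedModel) -> AnnotationBundle:
    return generate_dataset(model).bundle


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, str]:
    """Write the six pipeline inputs plus ground truth and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    f = DATASET_FILENAMES
    write_edgelist(dataset.network, out / f["network"])
    model = dataset.model
    n_cols = model.cycles * N_TIMESTAMPS
    with open(out / f["expression"], "w") as fh:
        header = [f"c{c + 1}t{t + 1}" for c in range(model.cycles) for t in range(N_TIMESTAMPS)]
        fh.write("gene\t" + "\t".join(header) + "\n")
        for gene in sorted(dataset.expression):
            vals = dataset.expression[gene]
            assert len(vals) == n_cols
            fh.write(gene + "\t" + "\t".join(f"{v:.6f}" for v in vals) + "\n")
    with open(out / f["localization"], "w") as fh:
        for v, term in sorted(dataset.localization_rows):
            fh.write(f"{v}\t{term}\n")
    with open(out / f["go"], "w") as fh:
        for v, term in sorted(dataset.go_rows):
            fh.write(f"{v}\t{term}\n")
    with open(out / f["essential"], "w") as fh:
        for v in sorted(dataset.bundle.essential):
            fh.write(v + "\n")
    with open(out / f["reference"], "w") as fh:
        for members in dataset.truth.complexes:
            fh.write("\t".join(sorted(members)) + "\n")
    manifest = {
        "model": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in vars(model).items()
        },
        "n_nodes": dataset.network.n_nodes,
        "n_edges": dataset.network.n_edges,
        "n_complexes": len(dataset.truth),
        "files": {k: v for k, v in f.items() if k != "manifest"},
    }
    with open(out / f["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(out / v) for k, v in f.items()}
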