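"""End-to-end orchestration: inputs -> dynamic networks -> weights -> cores
-> pollination -> merged catalog -> optional evaluation."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .cores import MiningConfig, find_cores
from .dynamic import build_subnetworks, make_profiles
from .evaluation import MATCH_OS_THRESHOLD, MatchResult, match_catalogs
from .io_formats import (
    ComplexCatalog,
    StaticNetwork,
    read_annotations,
    read_complexes,
    read_edgelist,
    read_expression,
    write_complexes,
)
from .pollination import IFPAConfig, merge_and_filter, run_ifpa
from .weights import AnnotationBundle, weight_subnetwork

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "detect_complexes", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs and file paths of one pipeline run."""

    network: str = ""
    expression: str = ""
    localization: str = ""
    go: str = ""
    essential: str = ""
    reference: str = ""
    out_dir: str = ""
    dt: float = 0.25
    thr: float = 0.2
    max_iter: int = 100
    rng_seed: int = 0
    overlap_filter: float = 0.8
    os_threshold: float = MATCH_OS_THRESHOLD
    cycles: int = 3


@dataclass
class PipelineResult:
    catalog: ComplexCatalog
    metrics: MatchResult | None
    manifest: dict = field(default_factory=dict)


def detect_complexes(
    network: StaticNetwork,
    expression: dict[str, list[float]],
    bundle: AnnotationBundle,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run detection on in-memory inputs; evaluation is left to the caller."""
    config = config or RunConfig()
    profiles = make_profiles(expression, cycles=config.cycles)
    subnets = build_subnetworks(network, profiles)
    mining = MiningConfig(dt=config.dt)
    ifpa = IFPAConfig(
        thr=config.thr,
        max_iter=config.max_iter,
        rng_seed=config.rng_seed,
        overlap_filter=config.overlap_filter,
    )
    per_timestamp = []
    counts = []
    for sub in subnets:
        mrdpn = weight_subnetwork(sub, bundle)
        cores = find_cores(mrdpn, mining)
        complexes = run_ifpa(cores, mrdpn, ifpa)
        per_timestamp.append(complexes)
        n_core_nodes = sum(len(c.members) for c in cores)
        counts.append(
            {
                "timestamp": sub.timestamp,
                "proteins": sub.graph.number_of_nodes(),
                "interactions": sub.graph.number_of_edges(),
                "cores": len(cores),
                "pollen": sub.graph.number_of_nodes() - n_core_nodes,
            }
        )
        logger.info(
            "t=%d: %d proteins, %d interactions, %d cores",
            sub.timestamp, counts[-1]["proteins"], counts[-1]["interactions"], len(cores),
        )
    catalog = merge_and_filter(per_timestamp, ifpa)
    manifest = {
        "version": __version__,
        "parameters": {
            "dt": config.dt,
            "thr": config.thr,
            "max_iter": config.max_iter,
            "rng_seed": config.rng_seed,
            "overlap_filter": config.overlap_filter,
            "os_threshold": config.os_threshold,
            "cycles": config.cycles,
        },
        "per_timestamp": counts,
        "n_predicted": len(catalog),
    }
    return PipelineResult(catalog=catalog, metrics=None, manifest=manifest)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-to-file pipeline: read inputs, detect, optionally evaluate, write outputs."""
    for label, path in (
        ("--network", config.network),
        ("--expr", config.expression),
    ):
        if not path or not Path(path).is_file():
            raise FileNotFoundError(f"missing required input {label}: {path!r}")
    network = read_edgelist(config.network)
    expression = read_expression(config.expression, cycles=config.cycles)
    bundle = AnnotationBundle(
        essential=read_annotations(config.essential, "essential") if config.essential else set(),
        scl=read_annotations(config.localization, "localization") if config.localization else {},
        go=read_annotations(config.go, "go") if config.go else {},
    )
    result = detect_complexes(network, expression, bundle, config)
    result.manifest["inputs"] = {
        "network": config.network,
        "expression": config.expression,
        "localization": config.localization,
        "go": config.go,
        "essential": config.essential,
        "reference": config.reference,
    }
    if config.reference:
        reference = read_complexes(config.reference)
        result.metrics = match_catalogs(
            result.catalog, reference, os_threshold=config.os_threshold
        )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_complexes(result.catalog, out / "predicted_complexes.txt")
        if result.metrics is not None:
            with open(out / "metrics.json", "w") as fh:
                json.dump(asdict(result.metrics), fh, indent=2, sort_keys=True)
                fh.write("\n")
        with open(out / "manifest.json", "w") as fh:
            json.dump(result.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return result
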