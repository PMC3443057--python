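"""End-to-end orchestration of the core-module discovery pipeline.

Stages: GO cluster assignment -> weighted co-expression networks ->
size-capped betweenness partitioning -> module differential-expression
scoring and TRM ranking -> mutation-enrichment testing -> core modules.
Downstream: topology summaries, cross-dataset relatedness and the
neighbor-joining tree.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .gn_partition import DEFAULT_SIZE_LIMIT, partition, write_module_table
from .go_network import assign_go_clusters, build_go_network
from .mutation_core import (
    DEFAULT_ALPHA,
    core_modules,
    mm_enrichment_score,
    test_all_modules,
    write_core_table,
)
from .psage import gene_t_scores, rank_modules, score_modules, write_score_table

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "build_networks",
    "partition_networks",
    "select_trms",
    "trm_genes",
    "identify_core_modules",
    "run_core_module_pipeline",
]


@dataclass
class PipelineConfig:
    """Knobs for a pipeline run; defaults follow the published procedure
    (module size limit 20, top-100 TRMs, Fisher alpha 0.05, cutoff 0)."""

    correlation: str = "pearson"
    min_cluster_size: int = 3
    size_limit: int = DEFAULT_SIZE_LIMIT
    trm_k: int = 100
    trg_m: int = None  # defaults to trm_k
    fisher_alpha: float = DEFAULT_ALPHA
    relatedness_cutoff: int = 0
    equal_var: bool = False
    betweenness_mode: str = "divide"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    clusters: list
    networks: list
    modules: list
    t_scores: dict
    ranked: list  # ModuleScore, sorted by p
    universe: set  # genes appearing in any GO network
    enrichment: list = field(default_factory=list)
    core_ids: list = field(default_factory=list)
    core_mutated_genes: set = field(default_factory=set)
    mm_score: float = None

    @property
    def trm_ids(self) -> set:
        return {s.module_id for s in self.ranked if s.is_trm}

    def trm_gene_union(self) -> set:
        by_id = {m.id: m for m in self.modules}
        genes: set = set()
        for mid in self.trm_ids:
            genes |= set(by_id[mid].genes)
        return genes


def build_networks(study, gene_sets, interactions, config: PipelineConfig):
    clusters = assign_go_clusters(gene_sets, study, config.min_cluster_size)
    networks = [
        build_go_network(c, interactions, study, config.correlation)
        for c in clusters
    ]
    return clusters, networks


def partition_networks(networks, config: PipelineConfig):
    modules = []
    for net in networks:
        modules.extend(
            partition(net, config.size_limit, mode=config.betweenness_mode)
        )
    logger.info("partitioned %d network(s) into %d module(s)", len(networks),
                len(modules))
    return modules


def select_trms(study, modules, config: PipelineConfig):
    """Score and rank modules; K is clamped to the module count."""
    t_scores = gene_t_scores(study, equal_var=config.equal_var)
    scores = score_modules(modules, t_scores)
    k = min(config.trm_k, len(scores))
    ranked = rank_modules(scores, k)
    return t_scores, ranked


def trm_genes(study, gene_sets, interactions, config: PipelineConfig) -> set:
    """Union of genes in the top-ranked modules (used by reproducibility)."""
    _, networks = build_networks(study, gene_sets, interactions, config)
    modules = partition_networks(networks, config)
    if not modules:
        return set()
    _, ranked = select_trms(study, modules, config)
    trm_ids = {s.module_id for s in ranked if s.is_trm}
    genes: set = set()
    for m in modules:
        if m.id in trm_ids:
            genes |= set(m.genes)
    return genes


def identify_core_modules(
    study, gene_sets, interactions, mutated: set, config: PipelineConfig = None
) -> PipelineResult:
    """Run the four discovery stages for one dataset."""
    config = config or PipelineConfig()
    clusters, networks = build_networks(study, gene_sets, interactions, config)
    modules = partition_networks(networks, config)
    universe = set().union(*(c.genes for c in clusters)) if clusters else set()
    result = PipelineResult(
        clusters=clusters,
        networks=networks,
        modules=modules,
        t_scores={},
        ranked=[],
        universe=universe,
    )
    if not modules:
        logger.warning("no modules found; nothing to score")
        return result
    result.t_scores, result.ranked = select_trms(study, modules, config)
    result.enrichment = test_all_modules(
        modules, set(mutated), universe, config.fisher_alpha
    )
    result.core_ids = core_modules(result.enrichment, result.ranked)
    by_id = {m.id: m for m in modules}
    for mid in result.core_ids:
        result.core_mutated_genes |= set(by_id[mid].genes) & set(mutated)
    try:
        result.mm_score = mm_enrichment_score(result.enrichment, result.ranked)
    except ValueError:
        result.mm_score = None
    logger.info(
        "%d module(s): %d TRMs, %d MMs, %d core",
        len(modules),
        len(result.trm_ids),
        sum(r.is_mm for r in result.enrichment),
        len(result.core_ids),
    )
    return result


def run_core_module_pipeline(
    study, gene_sets, interactions, mutated, config, outdir
) -> Path:
    """Run one dataset end to end and write all stage tables + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = identify_core_modules(study, gene_sets, interactions, mutated, config)
    write_module_table(result.modules, outdir / "modules.tsv")
    write_score_table(result.ranked, outdir / "scores.tsv")
    with open(outdir / "enrichment.tsv", "w") as fh:
        fh.write("module_id\tn_mutated\tsize\tfisher_p\tis_MM\n")
        for r in result.enrichment:
            fh.write(
                f"{r.module_id}\t{r.a}\t{r.module_size}\t{r.fisher_p:.6g}\t"
                f"{int(r.is_mm)}\n"
            )
    write_core_table(
        result.enrichment, result.ranked, result.modules, outdir / "core_modules.tsv"
    )
    _write_manifest(result, config, outdir / "manifest.json", study)
    return outdir


def _write_manifest(result, config, path, study) -> None:
    import networkx
    import numpy
    import scipy

    manifest = {
        "package_version": __version__,
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "networkx": networkx.__version__,
        },
        "config": config.to_dict(),
        "dataset": study.name,
        "counts": {
            "genes": len(study.genes),
            "samples": len(study.samples),
            "go_clusters": len(result.clusters),
            "modules": len(result.modules),
            "trms": len(result.trm_ids),
            "mms": int(sum(r.is_mm for r in result.enrichment)),
            "core_modules": len(result.core_ids),
        },
        "mm_enrichment_score": result.mm_score,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
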