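"""Synthetic studies with planted ground truth.

Generates, fully seed-deterministically, the four inputs the pipeline
consumes — expression matrix, gene-set collection, interaction network and
mutation catalog — with planted differentially expressed, co-expressed,
mutation-enriched modules, so every stage can be tested without external
data.

Planted module genes receive a shared latent factor (pairwise correlation
exactly rho), a mean shift delta in class B, dense interactions among
themselves and an elevated mutation rate.  Background genes are i.i.d.
standard normal; background interactions are sprinkled inside gene sets so
noise networks still produce modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_prep import (
    ExpressionStudy,
    GeneSetCollection,
    InteractionNetwork,
    MutationCatalog,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "MultitypeLayout",
    "MultitypeResult",
    "generate_study",
    "generate_multitype_layout",
]


@dataclass
class SyntheticSpec:
    n_genes: int = 500
    n_samples_per_class: int = 20
    n_go_sets: int = 50  # noise sets, in addition to the planted hosts
    go_size_mean: float = 20.0
    go_size_sd: float = 4.0
    n_planted: int = 3
    planted_size: int = 8
    delta: float = 2.0  # class-B mean shift of planted genes
    rho: float = 0.6  # pairwise correlation within a planted module
    p_in: float = 0.9  # interaction probability within planted modules
    p_background: float = 0.15  # interaction probability within any gene set
    mutation_rate: float = 0.1
    enrichment_multiplier: float = 5.0
    condition: str = "typeA"
    name: str = "synthetic"
    seed: int = 0

    def validate(self) -> None:
        for p in (self.rho, self.p_in, self.p_background, self.mutation_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.planted_size > self.go_size_mean:
            raise ValueError("planted module larger than its host GO set")
        if self.n_planted * self.planted_size > self.n_genes:
            raise ValueError("planted modules do not fit in the gene universe")


@dataclass
class GroundTruth:
    planted_modules: list  # list of frozensets
    de_genes: set
    mutated_genes: set


def _gene_names(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _draw_set_size(rng, spec: SyntheticSpec, minimum: int) -> int:
    size = int(round(rng.normal(spec.go_size_mean, spec.go_size_sd)))
    return max(minimum, min(size, spec.n_genes))


def _expression(rng, spec, genes, planted, extra_planted=()):
    """Gene x sample matrix; planted blocks share a factor and a B shift."""
    n_a = n_b = spec.n_samples_per_class
    n_samples = n_a + n_b
    values = rng.standard_normal((len(genes), n_samples))
    idx = {g: i for i, g in enumerate(genes)}
    for block in list(planted) + list(extra_planted):
        factor = rng.standard_normal(n_samples)
        for g in block:
            eps = rng.standard_normal(n_samples)
            values[idx[g]] = np.sqrt(spec.rho) * factor + np.sqrt(1 - spec.rho) * eps
    for block in planted:
        for g in block:
            values[idx[g], n_a:] += spec.delta
    samples = [f"A{i:02d}" for i in range(1, n_a + 1)] + [
        f"B{i:02d}" for i in range(1, n_b + 1)
    ]
    labels = {s: s[0] for s in samples}
    return samples, labels, values


def _interactions(rng, spec, gene_sets, planted) -> InteractionNetwork:
    pairs = []
    for block, p in [(b, spec.p_in) for b in planted] + [
        (s, spec.p_background) for s in gene_sets.values()
    ]:
        members = sorted(block)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < p:
                    pairs.append((members[i], members[j]))
    return InteractionNetwork.from_edge_pairs(pairs)


def _mutations(rng, spec, genes, planted) -> set:
    planted_genes = set().union(*planted) if planted else set()
    mutated = set()
    rate_in = min(1.0, spec.mutation_rate * spec.enrichment_multiplier)
    for g in genes:
        rate = rate_in if g in planted_genes else spec.mutation_rate
        if rng.random() < rate:
            mutated.add(g)
    return mutated


def generate_study(spec: SyntheticSpec):
    """Generate one complete synthetic dataset.

    Returns ``(study, gene_sets, interactions, catalog, truth)``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    shuffled = list(rng.permutation(genes))
    planted = [
        frozenset(shuffled[i * spec.planted_size : (i + 1) * spec.planted_size])
        for i in range(spec.n_planted)
    ]
    reserved = set().union(*planted) if planted else set()
    free = [g for g in shuffled if g not in reserved]

    sets = {}
    for i, block in enumerate(planted):
        size = _draw_set_size(rng, spec, spec.planted_size + 2)
        pad = list(rng.choice(free, size=min(size - len(block), len(free)),
                              replace=False))
        sets[f"HOST{i + 1:03d}"] = set(block) | set(pad)
    for i in range(spec.n_go_sets):
        size = _draw_set_size(rng, spec, 5)
        sets[f"NOISE{i + 1:03d}"] = set(
            rng.choice(genes, size=min(size, len(genes)), replace=False)
        )
    collection = GeneSetCollection(sets=sets, source="synthetic")

    samples, labels, values = _expression(rng, spec, genes, planted)
    study = ExpressionStudy(
        genes=genes, samples=samples, values=values, labels=labels, name=spec.name
    )
    network = _interactions(rng, spec, sets, planted)
    mutated = _mutations(rng, spec, genes, planted)
    catalog = MutationCatalog(conditions={spec.condition: mutated})
    truth = GroundTruth(
        planted_modules=planted,
        de_genes=set().union(*planted) if spec.delta != 0 and planted else set(),
        mutated_genes=mutated,
    )
    return study, collection, network, catalog, truth


# ---------------------------------------------------------------------------
# multi-dataset / multi-type layouts
# ---------------------------------------------------------------------------


@dataclass
class MultitypeLayout:
    """Several datasets over a shared gene space and interaction network.

    ``types`` maps cancer-type name -> list of 1 or 2 dataset names.  The
    two types named in ``shared_types`` plant a common block of
    ``n_shared_genes`` mutated genes; all other planted genes are private
    to their dataset.
    """

    base: SyntheticSpec = field(default_factory=SyntheticSpec)
    types: dict = field(default_factory=dict)
    shared_types: tuple = ()
    n_shared_genes: int = 5

    def validate(self) -> None:
        self.base.validate()
        if not self.types:
            raise ValueError("layout names no types")
        for typ, datasets in self.types.items():
            if not 1 <= len(datasets) <= 2:
                raise ValueError(f"type {typ!r} must have 1 or 2 datasets")
        for typ in self.shared_types:
            if typ not in self.types:
                raise ValueError(f"shared type {typ!r} not in layout")
        if self.n_shared_genes > self.base.planted_size:
            raise ValueError("shared block larger than a planted module")


@dataclass
class MultitypeResult:
    studies: dict  # dataset -> ExpressionStudy
    gene_sets: GeneSetCollection
    interactions: InteractionNetwork
    catalog: MutationCatalog  # one condition per dataset
    dataset_types: dict  # dataset -> type
    truth: dict  # dataset -> GroundTruth
    shared_genes: frozenset


def generate_multitype_layout(layout: MultitypeLayout) -> MultitypeResult:
    """Generate one study per dataset over a common gene universe."""
    layout.validate()
    spec = layout.base
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    dataset_types = {
        ds: typ for typ, datasets in layout.types.items() for ds in datasets
    }
    shared_datasets = [
        ds for ds in dataset_types if dataset_types[ds] in layout.shared_types
    ]

    shuffled = list(rng.permutation(genes))
    cursor = 0
    shared_block = shuffled[cursor : cursor + layout.n_shared_genes]
    cursor += layout.n_shared_genes

    planted_by_ds: dict = {}
    for ds in sorted(dataset_types):
        blocks = []
        for i in range(spec.n_planted):
            if i == 0 and ds in shared_datasets:
                pad = shuffled[
                    cursor : cursor + spec.planted_size - layout.n_shared_genes
                ]
                cursor += len(pad)
                blocks.append(frozenset(shared_block) | frozenset(pad))
            else:
                block = shuffled[cursor : cursor + spec.planted_size]
                cursor += spec.planted_size
                blocks.append(frozenset(block))
        if cursor > len(shuffled):
            raise ValueError("gene universe too small for the layout")
        planted_by_ds[ds] = blocks

    # one shared gene-set collection hosting every dataset's planted modules
    reserved = set().union(*(set().union(*b) for b in planted_by_ds.values()))
    free = [g for g in genes if g not in reserved]
    sets = {}
    for ds in sorted(planted_by_ds):
        for i, block in enumerate(planted_by_ds[ds]):
            size = _draw_set_size(rng, spec, spec.planted_size + 2)
            pad = list(
                rng.choice(free, size=min(size - len(block), len(free)),
                           replace=False)
            )
            sets[f"HOST_{ds}_{i + 1:02d}"] = set(block) | set(pad)
    for i in range(spec.n_go_sets):
        size = _draw_set_size(rng, spec, 5)
        sets[f"NOISE{i + 1:03d}"] = set(
            rng.choice(genes, size=min(size, len(genes)), replace=False)
        )
    collection = GeneSetCollection(sets=sets, source="synthetic-multitype")

    all_planted = [b for ds in sorted(planted_by_ds) for b in planted_by_ds[ds]]
    network = _interactions(rng, spec, sets, all_planted)

    studies, truth, conditions = {}, {}, {}
    for ds in sorted(dataset_types):
        own = planted_by_ds[ds]
        others = [b for d2, blocks in planted_by_ds.items() if d2 != ds
                  for b in blocks]
        samples, labels, values = _expression(rng, spec, genes, own,
                                              extra_planted=others)
        studies[ds] = ExpressionStudy(
            genes=genes, samples=samples, values=values, labels=labels, name=ds
        )
        mutated = _mutations(rng, spec, genes, own)
        conditions[ds] = mutated
        truth[ds] = GroundTruth(
            planted_modules=own,
            de_genes=set().union(*own),
            mutated_genes=mutated,
        )
    return MultitypeResult(
        studies=studies,
        gene_sets=collection,
        interactions=network,
        catalog=MutationCatalog(conditions=conditions),
        dataset_types=dataset_types,
        truth=truth,
        shared_genes=frozenset(shared_block),
    )
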