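"""Network topology statistics and mutated-gene network analysis.

Statistics over an undirected graph's degree sequence:

* density = mean(k) / (N - 1)
* centralization = N/(N-2) * (max(k)/(N-1) - density)
* heterogeneity = variance(k) / mean(k)  (population variance)
* per-node clustering coefficient 2*e_n / (k_n * (k_n - 1))
* closeness(v) = 1 / sum of shortest-path distances from v

Also: the cross-dataset mutated-gene network, the per-gene cancer-type
score N (with half credit for appearing in one of a type's two datasets),
the closeness-vs-N median regression, and the general/type-specific
classification of mutated genes against permutation controls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .reproducibility import grubbs_test

logger = logging.getLogger(__name__)

__all__ = [
    "TopologySummary",
    "MutatedGeneNetwork",
    "topology_summary",
    "closeness",
    "all_closeness",
    "build_mutated_gene_network",
    "cancer_type_score",
    "closeness_vs_types_regression",
    "classify_mutated_genes",
    "GeneClassification",
]


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    mean_clustering: float  # over nodes with degree >= 2
    n_low_degree: int  # nodes with degree < 2 (clustering undefined)
    density: float
    centralization: float  # nan when n_nodes < 3
    heterogeneity: float
    closeness: dict  # node -> closeness


def topology_summary(g: nx.Graph, population_variance: bool = True) -> TopologySummary:
    """Compute the degree-sequence statistics for an undirected graph."""
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    k = np.array([d for _, d in g.degree()], dtype=float)
    mean_k = float(k.mean())
    density = mean_k / (n - 1) if n > 1 else 0.0
    if n >= 3:
        centralization = n / (n - 2) * (k.max() / (n - 1) - density)
    else:
        centralization = math.nan
        logger.warning("centralization undefined for n < 3 nodes")
    var_k = float(k.var(ddof=0 if population_variance else 1))
    heterogeneity = var_k / mean_k if mean_k > 0 else 0.0
    clust = nx.clustering(g)
    eligible = [v for v in g if g.degree(v) >= 2]
    mean_clustering = (
        float(np.mean([clust[v] for v in eligible])) if eligible else math.nan
    )
    return TopologySummary(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        mean_clustering=mean_clustering,
        n_low_degree=n - len(eligible),
        density=density,
        centralization=float(centralization),
        heterogeneity=heterogeneity,
        closeness=all_closeness(g),
    )


def closeness(g: nx.Graph, node) -> float:
    """Reciprocal of the summed shortest-path distances from ``node``.

    Distances are taken within the node's connected component; isolated
    nodes get closeness 0 by convention.
    """
    if node not in g:
        raise KeyError(f"node {node!r} not in graph")
    dists = nx.single_source_shortest_path_length(g, node)
    total = sum(d for v, d in dists.items() if v != node)
    if total == 0:
        return 0.0
    return 1.0 / total


def all_closeness(g: nx.Graph) -> dict:
    return {v: closeness(g, v) for v in g}


@dataclass
class MutatedGeneNetwork:
    """Mutated genes found in core modules, joined by known interactions."""

    graph: nx.Graph
    gene_datasets: dict  # gene -> set of dataset names
    gene_scores: dict  # gene -> N (cancer-type score)
    dataset_types: dict  # dataset -> cancer type


def cancer_type_score(gene, membership: dict, dataset_types: dict) -> float:
    """Number-of-cancer-types score N with the half-credit rule.

    ``membership`` maps dataset name -> bool (gene in that dataset's core
    modules).  Types with a single dataset contribute 1 when the gene is
    present; types with two datasets contribute 1 when the gene is present
    in both and 1/2 when present in exactly one.
    """
    by_type: dict = {}
    for ds, typ in dataset_types.items():
        by_type.setdefault(typ, []).append(ds)
    n = 0.0
    for typ, datasets in by_type.items():
        if len(datasets) > 2:
            raise ValueError(f"cancer type {typ!r} has more than 2 datasets")
        present = sum(bool(membership.get(ds, False)) for ds in datasets)
        if len(datasets) == 1:
            n += 1.0 if present else 0.0
        else:
            n += {0: 0.0, 1: 0.5, 2: 1.0}[present]
    return n


def build_mutated_gene_network(
    core_mutated: dict, interactions, dataset_types: dict
) -> MutatedGeneNetwork:
    """Assemble the cross-dataset network of core-module mutated genes.

    ``core_mutated`` maps dataset name -> set of mutated genes appearing in
    that dataset's core modules; edges come from the reference interaction
    network.
    """
    gene_datasets: dict = {}
    for ds, genes in core_mutated.items():
        for gene in genes:
            gene_datasets.setdefault(gene, set()).add(ds)
    g = nx.Graph()
    g.add_nodes_from(gene_datasets)
    for e in interactions.edges:
        u, v = tuple(e)
        if u in gene_datasets and v in gene_datasets:
            g.add_edge(u, v)
    gene_scores = {
        gene: cancer_type_score(
            gene, {ds: ds in present for ds in dataset_types}, dataset_types
        )
        for gene, present in gene_datasets.items()
    }
    return MutatedGeneNetwork(
        graph=g,
        gene_datasets=gene_datasets,
        gene_scores=gene_scores,
        dataset_types=dict(dataset_types),
    )


def closeness_vs_types_regression(network: MutatedGeneNetwork):
    """OLS of median closeness against the cancer-type score N.

    One point per distinct N level: (N, median closeness of genes at that
    level).  Returns (slope, intercept, r_squared).
    """
    clos = all_closeness(network.graph)
    levels: dict = {}
    for gene, n in network.gene_scores.items():
        levels.setdefault(n, []).append(clos[gene])
    if len(levels) < 2:
        raise ValueError("need >= 2 distinct N levels for a regression")
    xs = np.array(sorted(levels))
    ys = np.array([float(np.median(levels[x])) for x in xs])
    res = stats.linregress(xs, ys)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return float(res.slope), float(res.intercept), r2


@dataclass
class GeneClassification:
    general: set = field(default_factory=set)  # Grubbs outliers with N > 1
    type_specific: set = field(default_factory=set)  # Grubbs outliers, N <= 1
    unstable: set = field(default_factory=set)  # failed the permutation test
    stable_other: set = field(default_factory=set)


def classify_mutated_genes(
    observed: dict,
    permuted: dict,
    wilcoxon_alpha: float = 0.01,
    grubbs_alpha: float = 0.05,
) -> GeneClassification:
    """Split mutated genes into general / type-specific / unstable.

    ``observed`` maps gene -> N score; ``permuted`` maps gene -> sequence of
    N scores under label permutation (a gene absent from the permuted core
    modules scores 0).  A gene is stable when a one-sided Wilcoxon
    signed-rank test finds its permuted scores significantly below the
    observed score.  Stable genes split at N > 1; within each group an
    iterative one-tailed Grubbs test flags the outlier genes.
    """
    if not permuted:
        raise ValueError("permutation N distributions are required")
    out = GeneClassification()
    stable = []
    for gene, n_obs in observed.items():
        perm = np.asarray(permuted.get(gene, []), dtype=float)
        if perm.size == 0:
            raise ValueError(f"no permutation scores for gene {gene!r}")
        diffs = perm - n_obs
        if np.all(diffs == 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(diffs, alternative="less").pvalue)
        if p < wilcoxon_alpha:
            stable.append(gene)
        else:
            out.unstable.add(gene)
    high = [g for g in stable if observed[g] > 1]
    low = [g for g in stable if observed[g] <= 1]
    for group, target in ((high, out.general), (low, out.type_specific)):
        if len(group) >= 3:
            vals = np.array([observed[g] for g in group])
            idx = grubbs_test(vals, one_tail_alpha=grubbs_alpha, return_indices=True)
            target.update(group[i] for i in idx)
    out.stable_other = set(stable) - out.general - out.type_specific
    return out


def write_node_annotation(network: MutatedGeneNetwork, path) -> None:
    """TSV export: gene, N, datasets, closeness, degree, clustering."""
    clos = all_closeness(network.graph)
    clust = nx.clustering(network.graph)
    with open(path, "w") as fh:
        fh.write("gene\tN\tdatasets\tcloseness\tdegree\tclustering\n")
        for gene in sorted(network.graph):
            fh.write(
                f"{gene}\t{network.gene_scores[gene]:g}\t"
                + ",".join(sorted(network.gene_datasets[gene]))
                + f"\t{clos[gene]:.6g}\t{network.graph.degree(gene)}\t"
                f"{clust[gene]:.6g}\n"
            )
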