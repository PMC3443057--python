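"""GO-constrained co-expression networks.

Each gene-set ("GO cluster") induces a subgraph of the global interaction
network restricted to genes measured in the study; edges are weighted by the
absolute correlation of the two genes' expression profiles across all
samples (both conditions pooled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_prep import ExpressionStudy, GeneSetCollection, InteractionNetwork

logger = logging.getLogger(__name__)

#: weight assigned to edges whose correlation is undefined (zero variance)
EPSILON_WEIGHT = 1e-6

__all__ = [
    "GoCluster",
    "GoNetwork",
    "EPSILON_WEIGHT",
    "assign_go_clusters",
    "coexpression_weight",
    "build_go_network",
]


@dataclass(frozen=True)
class GoCluster:
    """Intersection of one gene set with the study's measured genes."""

    name: str
    genes: frozenset


@dataclass
class GoNetwork:
    """One GO cluster's interaction subgraph with co-expression weights.

    ``edges`` maps frozenset({u, v}) -> weight in [0, 1].  Isolated nodes
    are kept in ``nodes``; the partitioner discards them later.
    """

    cluster: GoCluster
    nodes: set
    edges: dict
    correlation_kind: str = "pearson"

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e, w in self.edges.items():
            u, v = sorted(e)
            g.add_edge(u, v, weight=w)
        return g


def assign_go_clusters(
    collection: GeneSetCollection, study: ExpressionStudy, min_size: int = 3
) -> list:
    """Intersect each gene set with the study genes.

    Emits one :class:`GoCluster` per set whose intersection has at least
    ``min_size`` members.  A gene may appear in several clusters.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if not collection.sets:
        raise ValueError("empty gene-set collection")
    study_genes = set(study.genes)
    clusters = []
    for name in sorted(collection.sets):
        inter = collection.sets[name] & study_genes
        if len(inter) >= min_size:
            clusters.append(GoCluster(name=name, genes=frozenset(inter)))
    if clusters:
        sizes = [len(c.genes) for c in clusters]
        logger.info(
            "assigned %d GO cluster(s), mean size %.1f", len(clusters), np.mean(sizes)
        )
    return clusters


def coexpression_weight(x_i, x_j, kind: str = "pearson") -> float:
    """Absolute correlation between two expression vectors.

    Returns |r| with r the Pearson (or Spearman) correlation.  If either
    vector has zero variance the weight is floored at ``EPSILON_WEIGHT``
    rather than dropped, preserving topology.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape or x_i.ndim != 1:
        raise ValueError("expression vectors must be 1-d and of equal length")
    if x_i.size < 3:
        raise ValueError("need at least 3 samples to correlate")
    if np.ptp(x_i) == 0 or np.ptp(x_j) == 0:
        logger.warning("zero-variance vector; edge weight floored at epsilon")
        return EPSILON_WEIGHT
    if kind == "pearson":
        r = stats.pearsonr(x_i, x_j).statistic
    elif kind == "spearman":
        r = stats.spearmanr(x_i, x_j).statistic
    else:
        raise ValueError(f"unknown correlation kind {kind!r}")
    if np.isnan(r):
        return EPSILON_WEIGHT
    return max(abs(float(r)), EPSILON_WEIGHT)


def build_go_network(
    cluster: GoCluster,
    interactions: InteractionNetwork,
    study: ExpressionStudy,
    kind: str = "pearson",
) -> GoNetwork:
    """Keep interaction edges internal to the cluster, weight by |cor|."""
    idx = study.gene_index()
    edges = {}
    for e in interactions.edges:
        u, v = tuple(e)
        if u in cluster.genes and v in cluster.genes:
            w = coexpression_weight(study.values[idx[u]], study.values[idx[v]], kind)
            edges[frozenset((u, v))] = w
    return GoNetwork(
        cluster=cluster, nodes=set(cluster.genes), edges=edges, correlation_kind=kind
    )


def export_weighted_edges(network: GoNetwork, path) -> None:
    """Write a weighted edge-list TSV (gene1, gene2, weight)."""
    with open(path, "w") as fh:
        for e in sorted(network.edges, key=lambda e: tuple(sorted(e))):
            u, v = sorted(e)
            fh.write(f"{u}\t{v}\t{network.edges[e]:.6g}\n")
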