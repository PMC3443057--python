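"""Network relatedness, distances and the neighbor-joining tree.

Relatedness between two gene networks is the fraction of qualifying node
pairs: R = N0 / N1 where N0 counts unordered node pairs (one node from each
network) whose shortest-path distance in the reference interaction network
is within a cutoff, and N1 is the same count over the combined node set
against itself.  At cutoff 0 (distance 0 means the same node) this reduces
to the Jaccard index of the node sets.  D = 1 - R feeds neighbor joining.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RelatednessMatrix",
    "DistanceMatrix",
    "relatedness",
    "relatedness_matrix",
    "distance_matrix",
    "neighbor_joining",
    "write_phylip",
]


@dataclass
class RelatednessMatrix:
    labels: list
    values: np.ndarray  # symmetric, diag 1, entries in [0,1] (nan if undefined)
    cutoff: int


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray  # symmetric, zero diagonal


def _qualifying_pairs(nodes_a, nodes_b, dists_within_cutoff, cutoff) -> int:
    """Count unordered pairs {u, v}, u in A, v in B, with d(u, v) <= cutoff."""
    if cutoff == 0:
        return len(set(nodes_a) & set(nodes_b))
    seen = set()
    for u in nodes_a:
        near = dists_within_cutoff.get(u, {u: 0})
        for v in nodes_b:
            if v in near:
                seen.add(frozenset((u, v)) if u != v else (u,))
    return len(seen)


def relatedness(nodes_i, nodes_j, reference, cutoff: int = 0) -> float:
    """R between two node sets, measured on the reference network.

    ``reference`` is an :class:`~coremod.io_prep.InteractionNetwork` or a
    networkx graph; shortest paths are taken on the full reference network
    so that cross-network proximity counts.  Returns nan when N1 = 0.
    """
    if cutoff not in (0, 1, 2):
        raise ValueError("cutoff must be 0, 1 or 2")
    nodes_i, nodes_j = set(nodes_i), set(nodes_j)
    g = reference if isinstance(reference, nx.Graph) else reference.to_networkx()
    missing = (nodes_i | nodes_j) - set(g.nodes)
    if missing:
        raise ValueError(f"nodes not in reference network: {sorted(missing)[:5]}")
    union = nodes_i | nodes_j
    if cutoff == 0:
        dists = None
    else:
        dists = {
            u: nx.single_source_shortest_path_length(g, u, cutoff=cutoff)
            for u in union
        }
    n1 = _qualifying_pairs(union, union, dists, cutoff)
    if n1 == 0:
        logger.warning("relatedness undefined: no qualifying pairs in the union")
        return math.nan
    n0 = _qualifying_pairs(nodes_i, nodes_j, dists, cutoff)
    return n0 / n1


def relatedness_matrix(networks: dict, reference, cutoff: int = 0) -> RelatednessMatrix:
    """Pairwise R over a mapping label -> node set."""
    labels = sorted(networks)
    n = len(labels)
    r = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r[i, j] = r[j, i] = relatedness(
                networks[labels[i]], networks[labels[j]], reference, cutoff
            )
    return RelatednessMatrix(labels=labels, values=r, cutoff=cutoff)


def distance_matrix(r: RelatednessMatrix) -> DistanceMatrix:
    """Elementwise 1 - R with a zero diagonal; nan entries propagate."""
    d = 1.0 - r.values
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(r.labels), values=d)


def neighbor_joining(d: DistanceMatrix) -> str:
    """Standard neighbor joining; returns an unrooted Newick string.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch (logged).  Requires >= 3 taxa and finite distances.
    """
    labels = list(d.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    dm = np.array(d.values, dtype=float)
    if not np.all(np.isfinite(dm)):
        raise ValueError("distance matrix contains non-finite entries")
    # active nodes carry their Newick subtree strings
    nodes = list(labels)
    while len(nodes) > 3:
        n = len(nodes)
        totals = dm.sum(axis=1)
        # Q criterion; deterministic tie-break on (i, j)
        best, best_q = None, np.inf
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * dm[i, j] - totals[i] - totals[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * dm[i, j] + (totals[i] - totals[j]) / (2 * (n - 2))
        lj = dm[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new_label = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        new_d = 0.5 * (dm[i, :] + dm[j, :] - dm[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        new_dm = np.zeros((len(keep) + 1, len(keep) + 1))
        new_dm[:-1, :-1] = dm[np.ix_(keep, keep)]
        new_dm[-1, :-1] = new_dm[:-1, -1] = new_d[keep]
        nodes = [nodes[k] for k in keep] + [new_label]
        dm = new_dm
    # final three-taxon star: closed-form branch lengths
    a = 0.5 * (dm[0, 1] + dm[0, 2] - dm[1, 2])
    b = 0.5 * (dm[0, 1] + dm[1, 2] - dm[0, 2])
    c = 0.5 * (dm[0, 2] + dm[1, 2] - dm[0, 1])
    a, b = _clamp_pair(a, b)
    b, c = _clamp_pair(b, c)
    a, c = _clamp_pair(a, c)
    return (
        f"({nodes[0]}:{a:.10g},{nodes[1]}:{b:.10g},{nodes[2]}:{c:.10g});"
    )


def _clamp_pair(x: float, y: float):
    """Clamp a negative branch to 0, moving the deficit to its sister."""
    if x < 0:
        logger.info("clamped negative branch length %.4g", x)
        y += x
        x = 0.0
    if y < 0:
        logger.info("clamped negative branch length %.4g", y)
        x += y
        x = max(x, 0.0)
        y = 0.0
    return x, y


def write_phylip(d: DistanceMatrix, path) -> None:
    """Square PHYLIP-style distance matrix text."""
    with open(path, "w") as fh:
        fh.write(f"{len(d.labels)}\n")
        for i, label in enumerate(d.labels):
            row = " ".join(f"{x:.6f}" for x in d.values[i])
            fh.write(f"{label[:10]:<10s} {row}\n")
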