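"""Readers, writers and expression preprocessing.

File formats handled here are deliberately plain text: tab-delimited
expression matrices, GMT gene-set collections, two-column interaction edge
lists and ``condition<TAB>gene`` mutation catalogs.  All readers tolerate
CRLF line endings and trailing whitespace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy",
    "GeneSetCollection",
    "InteractionNetwork",
    "MutationCatalog",
    "read_expression_matrix",
    "write_expression_matrix",
    "impute_missing",
    "collapse_probes",
    "read_gene_sets",
    "write_gene_sets",
    "read_interactions",
    "write_interactions",
    "read_mutations",
    "write_mutations",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionStudy:
    """A gene x sample expression matrix with a binary sample labeling.

    Parameters
    ----------
    genes : list of str
        Row identifiers (gene symbols, or probe ids before collapsing).
    samples : list of str
        Column identifiers.
    values : ndarray of shape (n_genes, n_samples)
        Expression levels; missing entries are ``NaN``.
    labels : dict
        Maps every sample to one of exactly two class labels.
    name : str
        Dataset identifier.
    """

    genes: list
    samples: list
    values: np.ndarray
    labels: dict
    name: str = "study"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        missing = [s for s in self.samples if s not in self.labels]
        if missing:
            raise ValueError(f"samples without a class label: {missing[:5]}")

    @property
    def classes(self) -> tuple:
        """The two class labels, in sorted order."""
        cls = sorted(set(self.labels[s] for s in self.samples))
        if len(cls) != 2:
            raise ValueError(f"expected exactly 2 classes, found {cls}")
        return tuple(cls)

    def class_columns(self, label) -> np.ndarray:
        """Column indices of the samples carrying ``label``."""
        return np.array(
            [i for i, s in enumerate(self.samples) if self.labels[s] == label],
            dtype=int,
        )

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.genes)}

    def validate(self) -> None:
        """Raise if invariants are violated (unique genes, >=2 per class)."""
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols are not unique")
        for label in self.classes:
            if len(self.class_columns(label)) < 2:
                raise ValueError(f"class {label!r} has fewer than 2 samples")

    def with_values(self, values: np.ndarray) -> "ExpressionStudy":
        return replace(self, values=np.asarray(values, dtype=float))

    def subset_samples(self, samples: list) -> "ExpressionStudy":
        idx = [self.samples.index(s) for s in samples]
        return ExpressionStudy(
            genes=list(self.genes),
            samples=list(samples),
            values=self.values[:, idx],
            labels={s: self.labels[s] for s in samples},
            name=self.name,
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style)."""

    sets: dict
    source: str = ""

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if any(not str(g).strip() for g in members):
                raise ValueError(f"gene set {name!r} contains blank symbols")
            self.sets[name] = set(members)

    def __len__(self):
        return len(self.sets)


@dataclass
class InteractionNetwork:
    """An undirected interaction network without self-loops or duplicates."""

    nodes: set
    edges: set  # set of frozenset({u, v})

    @classmethod
    def from_edge_pairs(cls, pairs, extra_nodes=()) -> "InteractionNetwork":
        """Build from (u, v) pairs, collapsing duplicates and self-loops."""
        edges = set()
        nodes = set(extra_nodes)
        n_self, n_dup = 0, 0
        for u, v in pairs:
            u, v = str(u).strip(), str(v).strip()
            if not u or not v:
                continue
            nodes.update((u, v))
            if u == v:
                n_self += 1
                continue
            e = frozenset((u, v))
            if e in edges:
                n_dup += 1
            edges.add(e)
        if n_self or n_dup:
            logger.info(
                "collapsed %d self-loop(s) and %d duplicate edge(s)", n_self, n_dup
            )
        return cls(nodes=nodes, edges=edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g


@dataclass
class MutationCatalog:
    """Per-condition sets of mutated gene symbols."""

    conditions: dict

    def __post_init__(self):
        if not self.conditions:
            raise ValueError("mutation catalog has no conditions")
        for cond, genes in self.conditions.items():
            if any(not str(g).strip() for g in genes):
                raise ValueError(f"condition {cond!r} contains blank symbols")
            self.conditions[cond] = set(genes)


# ---------------------------------------------------------------------------
# expression matrix i/o
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}


def read_expression_matrix(path, label_spec, name=None) -> ExpressionStudy:
    """Read a tab-delimited expression matrix.

    First column holds gene/probe ids, header row holds sample ids.  Blank
    cells and ``NA`` become missing values.  ``label_spec`` maps each sample
    id to one of two class labels.
    """
    with open(path, "r", newline="") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        samples = [h.strip() for h in header[1:]]
        genes, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            gene = fields[0]
            row = []
            for col, cell in enumerate(fields[1 : len(samples) + 1], start=1):
                if cell in _MISSING_TOKENS:
                    row.append(np.nan)
                    continue
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at line {lineno} "
                        f"(gene {gene!r}, sample {samples[col - 1]!r})"
                    ) from None
            if len(row) < len(samples):
                row.extend([np.nan] * (len(samples) - len(row)))
            genes.append(gene)
            rows.append(row)
    unknown = sorted(set(label_spec) - set(samples))
    if unknown:
        raise ValueError(f"label_spec names unknown sample(s): {unknown}")
    unlabeled = [s for s in samples if s not in label_spec]
    if unlabeled:
        raise ValueError(f"samples without labels: {unlabeled[:5]}")
    return ExpressionStudy(
        genes=genes,
        samples=samples,
        values=np.array(rows, dtype=float),
        labels=dict(label_spec),
        name=name or str(path),
    )


def write_expression_matrix(study: ExpressionStudy, path) -> None:
    """Write a study back to tab-delimited text (NaN -> ``NA``)."""
    df = pd.DataFrame(study.values, index=study.genes, columns=study.samples)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def impute_missing(study: ExpressionStudy, k: int = 10) -> ExpressionStudy:
    """Fill missing entries by k-nearest-gene averaging.

    Each missing value is replaced by the mean, over the ``k`` genes nearest
    to the target gene (Euclidean distance on co-observed samples), of those
    genes' values in the affected sample.  Complete matrices pass through
    unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= len(study.genes):
        raise ValueError("k must be smaller than the number of genes")
    values = study.values.copy()
    if not np.isnan(values).any():
        return study.with_values(values)

    all_missing = np.isnan(values).all(axis=1)
    if all_missing.any():
        bad = [study.genes[i] for i in np.flatnonzero(all_missing)]
        raise ValueError(f"gene(s) missing in all samples: {bad[:5]}")
    frac = np.isnan(values).mean(axis=1)
    if (frac >= 0.5).any():
        bad = [study.genes[i] for i in np.flatnonzero(frac >= 0.5)]
        raise ValueError(f"gene(s) with >=50% missing entries: {bad[:5]}")

    n_genes = values.shape[0]
    for i in np.flatnonzero(np.isnan(values).any(axis=1)):
        missing_cols = np.flatnonzero(np.isnan(values[i]))
        # distance to every other gene over samples observed in both
        dists = np.full(n_genes, np.inf)
        for j in range(n_genes):
            if j == i:
                continue
            both = ~np.isnan(study.values[i]) & ~np.isnan(study.values[j])
            if not both.any():
                continue
            diff = study.values[i, both] - study.values[j, both]
            dists[j] = float(np.sqrt(np.sum(diff**2)))
        order = np.argsort(dists, kind="stable")
        for col in missing_cols:
            donors = [
                j
                for j in order
                if np.isfinite(dists[j]) and not np.isnan(study.values[j, col])
            ][:k]
            if not donors:
                raise ValueError(
                    f"cannot impute gene {study.genes[i]!r}: no donor genes "
                    f"observed in sample {study.samples[col]!r}"
                )
            values[i, col] = float(np.mean(study.values[donors, col]))
    return study.with_values(values)


def collapse_probes(study: ExpressionStudy, probe_map: dict) -> ExpressionStudy:
    """Collapse a probe-level study to gene level.

    ``probe_map`` maps probe id -> gene symbol.  Each gene's values are the
    arithmetic mean over its probes, per sample (NaN-aware).  Probes without
    a mapping are dropped.
    """
    mapped = [p for p in study.genes if p in probe_map]
    if not mapped:
        raise ValueError("no probe in the matrix maps to a gene symbol")
    n_dropped = len(study.genes) - len(mapped)
    if n_dropped:
        logger.info("dropped %d unmapped probe(s)", n_dropped)
    by_gene: dict = {}
    idx = study.gene_index()
    for probe in mapped:
        by_gene.setdefault(probe_map[probe], []).append(idx[probe])
    genes = sorted(by_gene)
    values = np.vstack(
        [np.nanmean(study.values[by_gene[g], :], axis=0) for g in genes]
    )
    return ExpressionStudy(
        genes=genes,
        samples=list(study.samples),
        values=values,
        labels=dict(study.labels),
        name=study.name,
    )


# ---------------------------------------------------------------------------
# gene sets / interactions / mutations
# ---------------------------------------------------------------------------


def read_gene_sets(path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line."""
    sets = {}
    with open(path, "r", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n").rstrip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: malformed GMT line {lineno} (need >= 3 fields)"
                )
            name = fields[0].strip()
            genes = {f.strip() for f in fields[2:] if f.strip()}
            sets[name] = genes
    return GeneSetCollection(sets=sets, source=str(path))


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = sorted(collection.sets[name])
            fh.write("\t".join([name, "na"] + genes) + "\n")


def read_interactions(path) -> InteractionNetwork:
    """Parse a two-column tab-delimited edge list."""
    pairs = []
    with open(path, "r", newline="") as fh:
        for line in fh:
            line = line.rstrip("\r\n").rstrip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: edge line with fewer than 2 columns")
            pairs.append((fields[0], fields[1]))
    return InteractionNetwork.from_edge_pairs(pairs)


def write_interactions(network: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{u}\t{v}\n")


def read_mutations(path) -> MutationCatalog:
    """Parse a ``condition<TAB>gene`` table."""
    conditions: dict = {}
    with open(path, "r", newline="") as fh:
        for line in fh:
            line = line.rstrip("\r\n").rstrip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: mutation line with fewer than 2 columns")
            conditions.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return MutationCatalog(conditions=conditions)


def write_mutations(catalog: MutationCatalog, path) -> None:
    with open(path, "w") as fh:
        for cond in sorted(catalog.conditions):
            for gene in sorted(catalog.conditions[cond]):
                fh.write(f"{cond}\t{gene}\n")
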