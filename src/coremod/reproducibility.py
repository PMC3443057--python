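"""Split-half and permutation reproducibility of module selection.

The protocol: split a study's samples in two (stratified by class), run the
module-selection pipeline on each half independently, and measure how many
selected genes the two halves share (intersection over union).  Shuffling
the class labels before splitting gives the permutation control; the
single-gene t-test ranking gives the gene-level comparator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_prep import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapResult",
    "overlap_percentage",
    "split_half_trial",
    "permutation_control",
    "grubbs_test",
    "write_trial_log",
]


@dataclass
class OverlapResult:
    overlap_fraction: float  # |intersection| / |union|; nan if both sets empty
    intersection: int
    union: int
    fisher_p: float  # nan when no universe was supplied


def overlap_percentage(set_a, set_b, universe=None) -> OverlapResult:
    """Intersection-over-union of two gene sets plus an overlap Fisher test.

    The Fisher p (one-sided, "greater") judges whether the observed overlap
    exceeds what random draws from ``universe`` would give.
    """
    set_a, set_b = set(set_a), set(set_b)
    if not set_a and not set_b:
        return OverlapResult(math.nan, 0, 0, math.nan)
    inter = set_a & set_b
    union = set_a | set_b
    fisher_p = math.nan
    if universe is not None:
        universe = set(universe)
        a = len(inter)
        b = len(set_a - set_b)
        c = len(set_b - set_a)
        d = len(universe - union)
        fisher_p = float(
            stats.fisher_exact([[a, b], [c, d]], alternative="greater").pvalue
        )
    return OverlapResult(len(inter) / len(union), len(inter), len(union), fisher_p)


def _stratified_split(study: ExpressionStudy, rng, stratified: bool = True):
    """Split samples into two halves; each half keeps >= 2 per class."""
    if stratified:
        half_a, half_b = [], []
        for label in study.classes:
            cols = [study.samples[i] for i in study.class_columns(label)]
            if len(cols) < 4:
                raise ValueError(
                    f"class {label!r} has {len(cols)} samples; need >= 4 to split"
                )
            cols = list(rng.permutation(cols))
            half_a.extend(cols[: len(cols) // 2])
            half_b.extend(cols[len(cols) // 2 :])
    else:
        cols = list(rng.permutation(study.samples))
        half_a, half_b = cols[: len(cols) // 2], cols[len(cols) // 2 :]
        for half in (half_a, half_b):
            counts = {c: 0 for c in study.classes}
            for s in half:
                counts[study.labels[s]] += 1
            if min(counts.values()) < 2:
                raise ValueError("unstratified split left a class with < 2 samples")
    return study.subset_samples(half_a), study.subset_samples(half_b)


def _select_genes(study, gene_sets, interactions, config, selection: str) -> set:
    from . import pipeline  # deferred: pipeline imports this module's grubbs

    if selection == "trm":
        return pipeline.trm_genes(study, gene_sets, interactions, config)
    if selection == "trg":
        from .psage import rank_genes_ttest

        m = config.trg_m or config.trm_k
        return set(rank_genes_ttest(study, min(m, len(study.genes))))
    raise ValueError(f"unknown selection {selection!r}")


def split_half_trial(
    study: ExpressionStudy,
    gene_sets,
    interactions,
    config,
    seed: int,
    stratified: bool = True,
    selection: str = "trm",
) -> OverlapResult:
    """One split-half trial: select genes on each half, return their overlap."""
    rng = np.random.default_rng(seed)
    half_a, half_b = _stratified_split(study, rng, stratified)
    genes_a = _select_genes(half_a, gene_sets, interactions, config, selection)
    genes_b = _select_genes(half_b, gene_sets, interactions, config, selection)
    return overlap_percentage(genes_a, genes_b, universe=set(study.genes))


def permutation_control(
    study: ExpressionStudy,
    gene_sets,
    interactions,
    config,
    n_permutations: int,
    trials_per_permutation: int = 1,
    seed: int = 0,
    selection: str = "trm",
) -> list:
    """Split-half overlaps after shuffling the class labels (control)."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_permutations):
        shuffled = rng.permutation([study.labels[s] for s in study.samples])
        permuted = ExpressionStudy(
            genes=list(study.genes),
            samples=list(study.samples),
            values=study.values,
            labels=dict(zip(study.samples, shuffled)),
            name=study.name + "_perm",
        )
        for _ in range(trials_per_permutation):
            trial_seed = int(rng.integers(0, 2**31 - 1))
            results.append(
                split_half_trial(
                    permuted, gene_sets, interactions, config, trial_seed,
                    selection=selection,
                )
            )
    return results


def grubbs_test(
    values,
    one_tail_alpha: float = 0.05,
    return_indices: bool = False,
    max_fraction: float = 0.2,
):
    """Iterative one-sided (upper-tail) Grubbs outlier detection.

    At each round G = (max x - mean) / sd is compared with the t-based
    critical value at the stated alpha; a detected outlier is removed and
    the test repeated.  Removal is capped at ``max_fraction`` of the input.
    Returns the outlier values (or their indices in the input).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Grubbs test needs >= 3 values")
    active = list(range(values.size))
    outliers = []
    max_removals = max(1, int(math.floor(max_fraction * values.size)))
    while len(active) >= 3 and len(outliers) < max_removals:
        x = values[active]
        sd = x.std(ddof=1)
        if sd == 0:
            logger.warning("zero standard deviation; no outliers detectable")
            break
        g = (x.max() - x.mean()) / sd
        n = len(active)
        t = stats.t.isf(one_tail_alpha / n, n - 2)
        g_crit = (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))
        if g <= g_crit:
            break
        drop = active[int(np.argmax(x))]
        outliers.append(drop)
        active.remove(drop)
    if return_indices:
        return outliers
    return [float(values[i]) for i in outliers]


def write_trial_log(rows, path) -> None:
    """TSV log: trial_id, seed, permuted, overlap_fraction, fisher_p."""
    with open(path, "w") as fh:
        fh.write("trial_id\tseed\tpermuted\toverlap_fraction\tfisher_p\n")
        for trial_id, seed, permuted, res in rows:
            fh.write(
                f"{trial_id}\t{seed}\t{int(permuted)}\t"
                f"{res.overlap_fraction:.6g}\t{res.fisher_p:.6g}\n"
            )
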