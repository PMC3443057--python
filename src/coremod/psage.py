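"""Module-level differential-expression scoring.

A module's SDS is the sum of squared per-gene two-sample t scores; its
p-value is the upper tail of a chi-square distribution with as many degrees
of freedom as the module has genes.  Modules ranked by ascending p-value
give the top-ranked modules (TRMs); the single-gene t-test ranking (TRGs)
is the comparator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_prep import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleScore",
    "gene_t_scores",
    "module_sds",
    "module_pvalue",
    "score_modules",
    "rank_modules",
    "rank_genes_ttest",
]


@dataclass
class ModuleScore:
    module_id: str
    n: int
    sds: float
    p_value: float
    rank: int = 0
    is_trm: bool = False


def gene_t_scores(study: ExpressionStudy, equal_var: bool = False) -> dict:
    """Per-gene two-sample t score between the two label classes.

    Welch's statistic by default (``equal_var=True`` pools the variances).
    Oriented as class A minus class B, classes in sorted label order; the
    sign is retained.  Degenerate genes (zero variance in both classes and
    equal means) score 0 with a warning.
    """
    a_label, b_label = study.classes
    a_cols = study.class_columns(a_label)
    b_cols = study.class_columns(b_label)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("both classes need >= 2 samples")
    a = study.values[:, a_cols]
    b = study.values[:, b_cols]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = stats.ttest_ind(a, b, axis=1, equal_var=equal_var).statistic
    bad = ~np.isfinite(t)
    if bad.any():
        logger.warning(
            "%d gene(s) with degenerate variance; t set to 0", int(bad.sum())
        )
        t = np.where(bad, 0.0, t)
    return {g: float(t[i]) for i, g in enumerate(study.genes)}


def module_sds(genes, t_scores: dict) -> float:
    """Sum of squared t scores over the module's genes."""
    missing = [g for g in genes if g not in t_scores]
    if missing:
        raise KeyError(f"genes without t scores: {sorted(missing)[:5]}")
    return float(sum(t_scores[g] ** 2 for g in genes))


def module_pvalue(sds: float, n: int) -> float:
    """Upper-tail chi-square probability of the SDS at df = module size."""
    if n < 1:
        raise ValueError("module size must be >= 1")
    if sds < 0:
        raise ValueError("SDS must be non-negative")
    return float(stats.chi2.sf(sds, df=n))


def score_modules(modules, t_scores: dict) -> list:
    """Score a list of modules; returns unranked :class:`ModuleScore`."""
    return [
        ModuleScore(
            module_id=m.id,
            n=len(m.genes),
            sds=module_sds(m.genes, t_scores),
            p_value=module_pvalue(module_sds(m.genes, t_scores), len(m.genes)),
        )
        for m in modules
    ]


def rank_modules(scores, k: int) -> list:
    """Rank ascending by p-value and flag the top ``k`` as TRMs.

    Ties broken by larger SDS, then module id.  Returns the scores sorted,
    with ``rank`` (1-based) and ``is_trm`` filled in.
    """
    if k > len(scores):
        raise ValueError(f"K={k} exceeds module count {len(scores)}")
    ranked = sorted(scores, key=lambda s: (s.p_value, -s.sds, s.module_id))
    for i, s in enumerate(ranked):
        s.rank = i + 1
        s.is_trm = i < k
    return ranked


def rank_genes_ttest(study: ExpressionStudy, m: int, equal_var: bool = False) -> list:
    """Top ``m`` genes by smallest two-sided t-test p-value (TRGs)."""
    if m > len(study.genes):
        raise ValueError(f"M={m} exceeds gene count")
    if m == 0:
        return []
    a_label, b_label = study.classes
    a = study.values[:, study.class_columns(a_label)]
    b = study.values[:, study.class_columns(b_label)]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    order = sorted(range(len(study.genes)), key=lambda i: (p[i], study.genes[i]))
    return [study.genes[i] for i in order[:m]]


def write_score_table(ranked, path) -> None:
    """TSV export: module_id, size, SDS, p_value, rank, is_TRM."""
    with open(path, "w") as fh:
        fh.write("module_id\tsize\tSDS\tp_value\trank\tis_TRM\n")
        for s in ranked:
            fh.write(
                f"{s.module_id}\t{s.n}\t{s.sds:.6g}\t{s.p_value:.6g}\t"
                f"{s.rank}\t{int(s.is_trm)}\n"
            )
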