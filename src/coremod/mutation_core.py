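"""Mutation enrichment and core-module calling.

A module is a mutated module (MM) when a one-sided Fisher exact test finds
significantly more mutated genes inside it than outside, judged against the
universe of genes eligible to enter modules.  Core modules are MMs that are
also top-ranked (TRM) for differential expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

DEFAULT_ALPHA = 0.05

__all__ = [
    "EnrichmentResult",
    "module_mutation_test",
    "test_all_modules",
    "core_modules",
    "mm_enrichment_score",
    "mutated_gene_fraction_ratio",
    "DEFAULT_ALPHA",
]


@dataclass
class EnrichmentResult:
    module_id: str
    a: int  # mutated genes in the module
    b: int  # non-mutated in the module
    c: int  # mutated outside
    d: int  # non-mutated outside
    fisher_p: float
    is_mm: bool

    @property
    def module_size(self) -> int:
        return self.a + self.b


def module_mutation_test(
    module, mutated: set, universe: set, alpha: float = DEFAULT_ALPHA
) -> EnrichmentResult:
    """One-sided ("greater") Fisher exact test of in-module mutation excess.

    The 2x2 table crosses (in module / not) with (mutated / not) over
    ``universe``.  Module genes must be a subset of the universe.
    """
    if not universe:
        raise ValueError("empty gene universe")
    genes = set(module.genes)
    if not genes <= universe:
        raise ValueError(f"module {module.id} has genes outside the universe")
    mutated = mutated & universe
    a = len(genes & mutated)
    b = len(genes) - a
    c = len(mutated) - a
    d = len(universe) - len(genes) - c
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater").pvalue)
    return EnrichmentResult(
        module_id=module.id, a=a, b=b, c=c, d=d, fisher_p=p, is_mm=p <= alpha
    )


def test_all_modules(modules, mutated: set, universe: set, alpha=DEFAULT_ALPHA):
    return [module_mutation_test(m, mutated, universe, alpha) for m in modules]


def core_modules(results, ranked_scores) -> list:
    """Module ids that are both MM and TRM."""
    trm_ids = {s.module_id for s in ranked_scores if s.is_trm}
    return sorted(r.module_id for r in results if r.is_mm and r.module_id in trm_ids)


def mm_enrichment_score(results, ranked_scores) -> float:
    """(fraction of TRMs that are MM) / (fraction of non-TRMs that are MM)."""
    trm_ids = {s.module_id for s in ranked_scores if s.is_trm}
    in_trm = [r for r in results if r.module_id in trm_ids]
    out_trm = [r for r in results if r.module_id not in trm_ids]
    if not in_trm or not out_trm:
        raise ValueError("both the TRM and non-TRM groups must be non-empty")
    f_in = sum(r.is_mm for r in in_trm) / len(in_trm)
    f_out = sum(r.is_mm for r in out_trm) / len(out_trm)
    if f_in == 0:
        return 0.0
    if f_out == 0:
        return math.inf
    return f_in / f_out


def mutated_gene_fraction_ratio(trm_genes: set, other_genes: set, mutated: set):
    """(fraction mutated among TRM genes) / (fraction mutated among others).

    Returns ``nan`` when no gene in either group is mutated, ``inf`` when
    mutations occur only inside the TRM genes.
    """
    if not trm_genes or not other_genes:
        raise ValueError("both gene sets must be non-empty")
    f_in = len(trm_genes & mutated) / len(trm_genes)
    f_out = len(other_genes & mutated) / len(other_genes)
    if f_in == 0 and f_out == 0:
        return math.nan
    if f_in == 0:
        return 0.0
    if f_out == 0:
        return math.inf
    return f_in / f_out


def write_core_table(results, ranked_scores, modules, path) -> None:
    """TSV export: module_id, genes, SDS, psage_p, fisher_p, n_mutated."""
    core = set(core_modules(results, ranked_scores))
    by_id = {m.id: m for m in modules}
    score_by_id = {s.module_id: s for s in ranked_scores}
    res_by_id = {r.module_id: r for r in results}
    with open(path, "w") as fh:
        fh.write("module_id\tgenes\tSDS\tpsage_p\tfisher_p\tn_mutated\n")
        for mid in sorted(core):
            s, r = score_by_id[mid], res_by_id[mid]
            fh.write(
                f"{mid}\t{','.join(sorted(by_id[mid].genes))}\t{s.sds:.6g}\t"
                f"{s.p_value:.6g}\t{r.fisher_p:.6g}\t{r.a}\n"
            )
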