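# coremod

Network-constrained discovery of **core gene modules**: gene modules that are
simultaneously top-ranked for two-condition differential expression and
significantly enriched for somatic mutations, inside GO-restricted
protein-interaction networks weighted by co-expression.

## What it does

For one expression dataset with a binary phenotype, a gene-set (GMT)
collection, a protein-interaction edge list and a mutated-gene catalog:

1. **GO networks** — intersect each gene set with the measured genes and keep
   only interaction edges internal to that set; weight each edge by the
   absolute Pearson (or Spearman) correlation of the two expression profiles.
2. **Partitioning** — divisive edge-betweenness clustering (betweenness of
   the unweighted topology divided by the edge weight), freezing every
   connected component that falls below a size limit (default 20) as a
   module; singletons are dropped.
3. **Module scoring** — each module's SDS is the sum of squared per-gene
   Welch t scores; p-values come from the upper tail of chi-square with
   df = module size. The K smallest p-values mark the top-ranked modules
   (TRMs, default K = 100). A single-gene t-test ranking (TRGs) is provided
   as the comparator.
4. **Mutation enrichment** — one-sided Fisher exact test of mutated-gene
   excess per module against the universe of genes that entered any GO
   network (mutated modules, MM, at p <= 0.05). **Core modules** = MM ∩ TRM.

Downstream analyses: network topology statistics (density, centralization,
heterogeneity, clustering, closeness), split-half / permutation
reproducibility with Fisher-overlap, Wilcoxon and iterative Grubbs tests,
per-gene cancer-type scores with the half-credit rule for two-dataset types,
closeness-vs-N median regression, cross-dataset network relatedness
(R = qualifying node-pair fraction; Jaccard at cutoff 0), D = 1 − R, and a
neighbor-joining tree in Newick format.

A fully seeded synthetic-data generator (`coremod.synthetic`) emits all four
input formats with planted co-expressed, differentially expressed,
mutation-enriched modules and multi-dataset / multi-type layouts, so the
entire pipeline is testable offline.

## CLI

```sh
# generate a synthetic dataset with planted signal
coremod simulate --out data/ --seed 1

# full single-dataset run (all four stages + manifest)
coremod run-all data/expression.tsv data/labels.tsv data/gene_sets.gmt \
    data/interactions.tsv data/mutations.tsv \
    --condition typeA --trm-k 100 --out runs/demo

# individual stages
coremod partition  <expression> <labels> <gmt> <edges> --out modules.tsv
coremod score      <expression> <labels> <gmt> <edges> --out scores.tsv
coremod enrich     <expression> <labels> <gmt> <edges> <mutations> \
    --condition typeA --out core.tsv
coremod topology   <edge-list>
coremod phylo      <condition-gene-table> <edge-list> --out ph/
coremod reproduce  <expression> <labels> <gmt> <edges> --trials 10 \
    --out trials.tsv
```

Input formats are plain text: tab-delimited expression matrix (first column
gene ids, header row sample ids, blank/`NA` cells = missing), two-column
`sample<TAB>class` labels, GMT gene sets, two-column edge list, and a
two-column `condition<TAB>gene` mutation catalog.

## Layout

```
src/coremod/
  io_prep.py          readers/writers, imputation, probe collapsing
  go_network.py       GO clusters + weighted co-expression networks
  gn_partition.py     size-capped divisive edge-betweenness partitioning
  psage.py            SDS / chi-square module scoring, TRM + TRG ranking
  mutation_core.py    Fisher enrichment, core modules, MM-enrichment score
  reproducibility.py  split-half, permutation control, overlap, Grubbs
  topology.py         degree-sequence statistics, N scores, classification
  phylo.py            relatedness, distances, neighbor joining, Newick
  synthetic.py        seeded generators with planted ground truth
  pipeline.py         stage orchestration and run manifests
  cli.py              click command group
```
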