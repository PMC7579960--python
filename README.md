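# netcoherence

Quantify how *coherent* a gene set's protein–protein-interaction (PPI)
network is — i.e. how much it behaves like a community within the global
interactome — in a way that can be compared across gene sets of different
sizes.

This matters for interpreting GWAS results: the genes mapped to a trait's
associated variants may form a tightly interacting module (suggesting a
focused molecular mechanism, and a target for intervention) or a diffuse,
random-looking collection. Raw connectivity statistics cannot be compared
across traits because trait gene lists differ wildly in size, and degree
distributions depend on network size. `netcoherence` implements a
size-normalized coherence estimate, a permutation significance test
against size-matched random networks, and greedy modularity for
comparison, for anyone who works with gene sets on an interactome
(GWAS follow-up, pathway curation, network biology methods work).

## The statistic

For a gene set *S* and a global PPI graph, each member gene *g* present in
the graph has an **internal degree** k_int(g) (interaction partners inside
*S*) and an **external degree** k_ext(g) (partners outside *S*), with
k_int + k_ext equal to *g*'s global degree. The raw coherence statistic is
the least-squares slope through the origin of the square-root degrees
x_g = √k_int(g), y_g = √k_ext(g):

    β = Σ x_g y_g / Σ x_g²

A perfect community (all edges internal) gives the horizontal line β = 0;
a random-like set with mostly external edges gives a steep slope. Because
β falls with network size, it is min–max normalized against size-matched
anchors: 30 high-coherence reference networks (10 from each of 3
pathway-style collections; median slope β_min) and random gene sets of the
same effective size (median slope β_max):

    coherence = (β − β_max) / (β_min − β_max)

so 0 is random-like, 1 is pathway-like, and values beyond 1 (more coherent
than the median reference pathway) are legal and meaningful. Significance
comes from a permutation test: random networks assembled to match the
phenotype's size *g* and number of non-zero interacting genes *n* are
scored with the same slope machinery, and p = (count + 1)/(n_perm + 1)
with the default tail counting random slopes ≤ β (small p = more coherent
than random). Modularity (Clauset–Newman–Moore greedy maximization) of
the internal subnetwork is reported alongside, as the two measures capture
distinct network properties.

Everything is testable without downloads: the `synthetic` module generates
interactomes with planted dense modules at known coherence levels and
serializes them in the exact dialects the readers parse (STRING-style
links file, GMT, GWAS-catalog-style phenotype TSV).

## Worked example

Simulate a 1000-gene background with 30 planted reference modules and six
phenotypes (two planted dense, two planted intermediate, two random
draws), then run the pipeline:

```sh
netcoherence simulate --out-dir demo --seed 11 --n-genes 1000
netcoherence coherence --config demo/config.yaml
netcoherence permtest --config demo/config.yaml --results demo/results/results.tsv
netcoherence report --results demo/results/results.tsv --out demo/results/summary.tsv
```

with `demo/config.yaml`:

```yaml
ppi_path: demo/ppi_links.txt
ppi_dialect: string
score_threshold: 500
reference_gmts: [demo/collection_a.gmt, demo/collection_b.gmt, demo/collection_c.gmt]
phenotype_path: demo/phenotypes.tsv
category_column: CATEGORY
n_random: 200
n_perm: 999
seed: 7
output_dir: demo/results
```

`demo/results/results.tsv` then contains (abridged):

| set_id | n_genes | slope | coherence | perm_p | modularity |
|---|---|---|---|---|---|
| pheno_high_0 | 40 | 0.614 | 1.01 | 0.001 | 0.034 |
| pheno_high_1 | 80 | 0.436 | 1.06 | 0.001 | 0.032 |
| pheno_medium_0 | 30 | 1.17 | 0.90 | 0.001 | 0.193 |
| pheno_medium_1 | 60 | 0.838 | 0.96 | 0.001 | 0.138 |
| pheno_random_0 | 25 | 5.11 | 0.11 | 0.298 | 0.594 |
| pheno_random_1 | 100 | 3.91 | 0.089 | 0.621 | 0.858 |

Reading it: the planted dense modules (internal wiring probability 0.8)
score coherence ≈ 1 — as coherent as the median reference module — and are
more coherent than every one of the 999 assembled random networks
(p = 1/1000, the smallest attainable value). The intermediate modules
land just below. The random draws sit near coherence 0 with
non-significant p, and their *high* modularity (0.59, 0.86) against *low*
coherence for the dense modules' single-community structure illustrates
that modularity and coherence measure different things. Raw slopes are
not comparable across rows (the two equally-wired `high` modules differ,
0.614 vs 0.436, purely by size); the normalized coherences are.

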