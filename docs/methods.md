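# Methods

## Model and assumptions

The package treats the global interactome as a simple undirected graph
over gene symbols. Confidence scores (STRING's 0–1000 `combined_score`)
are used once, as a hard edge filter (strictly greater than the
threshold, default 500); edges are never weighted downstream. A gene
set's network is the induced subgraph on its members present in the
interactome, without extracting the largest connected component — genes
with no in-set interactions but with outside interactions stay in the
table, because their external degrees carry information about how
embedded the set is.

The coherence statistic is the no-intercept least-squares slope of
√k_ext on √k_int over the set's degree table, β = Σxy/Σx². The square
root compresses the heavy tail of PPI degrees. Both axes are
transformed: this is the symmetric choice and gives the clean identity
β = 1 for a set whose genes each have k_int = k_ext. Genes with
k_int = 0 drop out of β algebraically but count toward the residual
degrees of freedom. The confidence interval is the normal-theory
no-intercept interval, β ± t(1−α/2, n−1)·se with se² = RSS/((n−1)Σx²),
at a default 95% level; the test suite cross-checks both β and the CI
against an independent no-intercept OLS fit.

Orientation matters and is fixed throughout: external degree is the
response, internal degree the regressor. High coherence therefore means
a *small* slope, and the min–max normalization (below) flips the scale
so that larger normalized values mean more coherence.

## Eligibility filters

Two pre-fit filters reject sets whose slope would be unstable or
undefined:

* fewer than 10 genes with k_int ≥ 1 (`min_nonzero`, configurable — a
  larger threshold is defensible for noisy interactomes);
* all retained genes sharing one identical internal degree, i.e. no
  internal degree distribution. The check covers k_int = 0 rows too: a
  table in which every gene has k_int = 0 is degenerate by the same
  logic (and is in practice caught by the first filter).

Set genes absent from the interactome are dropped with a logged count;
all "size" notions downstream (panel matching, permutation draws) use
the **effective size** — genes present in the network — because that is
the population the degree table is built on.

## Normalization

For a query of effective size g, a reference panel supplies two anchors:
β_min, the median slope of 30 high-coherence reference networks (10 per
collection from 3 pathway-style collections, chosen nearest in effective
size to g, ties broken lexicographically by set id), and β_max, the
median slope of 1000 (default; configurable) uniform random gene sets of
size g. Coherence is (β − β_max)/(β_min − β_max), deliberately unclamped:
values above 1 mean "more coherent than the median reference pathway"
and are reported as such. Confidence bounds are pushed through the same
map and re-ordered, since the map is decreasing. A panel whose anchors
coincide is an error state, not a silent zero. Reference sets are never
subsampled to force an exact size match — that would destroy the very
pathway structure they anchor — so the nearest-size selection logs when
the best match deviates more than 25% from the target. Panels are cached
per target size within a run, and each size's random draws come from a
dedicated seed substream, so a panel is identical whether it is built
first or last.

## Permutation test

The null mimics the observed phenotype's footprint. One null replicate:
draw uniform gene sets of size g; harvest from each draw the genes with
at least one interaction inside that draw ("non-zero interacting");
accumulate harvested genes (deduplicated) until at least n of them, the
observed count, are collected; score the combined set with the same
degree-table and slope machinery against the same interactome. The
assembled set is treated exactly like a phenotype (internal = within the
combined set, external = rest of the interactome), keeping the null
statistic exchangeable with the observed one. A draw cap (default
10,000 per assembly) turns a pathologically sparse interactome into an
explicit error rather than an endless loop.

With n_perm replicates (default 10,000; the desk-scale tests use
500–1000), p = (count + 1)/(n_perm + 1), so p is never 0 and its
minimum is 1/(n_perm + 1). Two tails are implemented. The default,
`coherent`, counts random slopes ≤ β_obs, so small p means
more-coherent-than-random — the direction in which significant
phenotypes are interpreted. The alternative `paper` tail counts random
slopes > β_obs, the literal published indicator function, retained for
audit; the two are exact complements on a shared random sample. The
published formula and the published interpretation of significance
disagree with each other, which is why both are available and the
discrepancy is documented rather than silently resolved.

## Modularity

Modularity Q is computed on the internal induced subgraph only, by
greedy agglomerative (Clauset–Newman–Moore) maximization as implemented
in networkx, with exhaustive-partition search as the test oracle on
graphs small enough to enumerate. It is reported per phenotype for the
coherence-vs-modularity comparison; no size normalization of Q is
attempted.

## Synthetic worlds

The generator emulates the three real inputs. The background interactome
is Erdős–Rényi (default n = 2000, p = 0.005, mean degree ≈ 10 — the
order of a score-thresholded PPI network) or Barabási–Albert
(`powerlaw`) when heavy-tailed degrees matter. Reference collections are
planted dense modules: default 3 collections × 10 modules, sizes 20–80,
internal wiring probability p_in = 0.6, external attachment at the
background density so module genes look background-typical from outside.
Phenotypes come in three levels: `high` (p_in = 0.8) and `medium`
(p_in = 0.3) are planted the same way; `random` is a uniform draw from
the edge-bearing interactome, which makes it exactly the population the
β_max anchor and the permutation null sample from. Planted modules are
wired on fresh, previously edgeless nodes added on top of the
background, and kept disjoint across modules, so each set's ground-truth
level is uncontaminated — a p_in = 1, p_out = 0 module is an exact
clique with zero external edges and slope exactly 0. After planting,
degree-0 nodes are pruned: the interactome is, as in real PPI exports,
the set of edge-bearing genes, and serialized worlds round-trip exactly
through the readers. Phenotype gene lists may still mention pruned
genes, which exercises the genes-without-PPI-annotation path the real
pipeline needs.

What the synthetic worlds do *not* emulate: the empirical STRING/BioGrid
degree distributions and their correlation structure, overlapping
pathways (module genes are disjoint by design), literature-curation
biases, or gene-symbol aliasing mess. Tests passing on these worlds
demonstrate that the statistics behave as designed — size independence,
anchor identities, planted-structure recovery — not that any particular
real phenotype's coherence value is correct.

## Numerical and design choices

* Strict inequality for score filtering (score > threshold).
* Multi-gene phenotype cells split on `;`, `,`, ` - `, ` x `
  (configurable); non-coding/antisense/readthrough exclusion is a
  user-supplied list plus optional regex patterns, not a bundled
  annotation database.
* Alias resolution is a user-supplied two-column table; strict mode
  drops unmapped symbols (the analogue of excluding unmappable genes).
* Sampling pools are sorted before every random draw, so results depend
  only on the seed, never on set iteration order; the run seed spawns
  per-stage substreams (per panel size, per phenotype for permutations),
  making reruns byte-identical and stages independently reproducible,
  including across `--threads` settings.
* Median of an even-length slope list is the midpoint of the central
  pair.
* A single-row degree table yields a zero-width CI (df = 0) rather than
  NaN bounds.
* Desk-scale test/acceptance runs use n_random = 50–200 panel draws and
  n_perm = 99–999 permutations on worlds of 600–2000 background genes;
  the statistics are the same code paths as the full-scale defaults
  (n_random = 1000, n_perm = 10,000).

## Known limitations

* Coherence inherits the chosen interactome's biases; values from
  different PPI sources are comparable only after normalization against
  panels built on the same source.
* The CI is a plain normal-theory interval on a count-derived
  statistic; after min–max normalization it loses its coverage
  interpretation, and the permutation p-value is the preferred
  significance statement.
* Very large gene sets can exceed the largest available reference
  module size; nearest-size matching then anchors β_min on smaller
  reference networks (logged when deviation exceeds 25%).
* Greedy modularity maximization is a heuristic; it attains the
  exhaustive optimum on the small oracle graphs in the test suite but
  is not guaranteed to on arbitrary graphs.
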