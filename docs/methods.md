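# Methods

## Model and procedure

The pipeline treats a comorbidity study as four deterministic stages.

**Gene lists.** A disorder list is an ordered set of canonical gene
symbols. Symbols are uppercased and optionally resolved through an
explicit alias table (many-to-one, no chains) before comparison;
duplicates after canonicalization are collapsed keeping the first
occurrence, with the collapse count logged so curation errors stay
visible. The shared-gene list is the intersection, ordered by first
appearance in the first list. Curation policy itself (which studies
count as evidence for a gene–disorder link, linkage-marker distance
rules, and so on) happens before this package and is out of its scope:
the curated lists are inputs.

**Over-representation analysis.** Each category of each annotation
collection is tested with the hypergeometric upper tail
P(X ≥ k | N, K, n), evaluated through `scipy.stats.hypergeom.sf`
(survival-function evaluation is numerically stable at any realistic
universe size; the test suite pins it to an exact-rational
probability-mass sum at 1e−12 relative tolerance). The background
defaults to the union of members across all loaded collections when no
explicit universe is given — the reproducible choice when a study's
reference set is unstated. Query genes outside the background are
dropped (logged); category members are restricted to the background and
categories outside the size window are not tested. Benjamini–Hochberg
adjustment (`scipy.stats.false_discovery_control`) is applied within
each collection separately, because each annotation database is a
separate testing family and enrichment servers report them separately.
A category is significant when FDR ≤ threshold and k ≥ 1.

**Network.** Significant categories and their query-overlap genes form
an undirected graph with membership edges only; by construction it is
bipartite across the gene/category divide, every category node has
degree ≥ 1, and the edge count equals Σ k over significant categories.
Genes with no significant membership are excluded by default (a flag
keeps them), matching how published comorbidity networks contain fewer
genes than the shared list when some shared genes are unannotated or
only in non-significant categories. Membership edges are undirected
because membership has no direction and the reported topology measures
are undirected.

**Topology.** Betweenness is Brandes' algorithm on unweighted shortest
paths (via `networkx`), endpoints never credited, normalized by
(n−1)(n−2)/2 over the whole graph rather than per component — the
NetworkAnalyzer convention, which keeps values in [0, 1] and comparable
across disconnected networks. Closeness uses the Wasserman–Faust
correction (r/ΣD scaled by r/(n−1) with r the reachable peers), so
disconnected networks are well defined and an isolated node scores 0.
Both are pinned against brute-force shortest-path-enumeration and BFS
oracles on seeded graphs. Node rankings sort descending by the measure
with ties broken ascending by node ID, making every report
deterministic. Betweenness histograms use half-open bins [a, a+w) with
the final bin closed at 1 (default width 0.1); counts always sum to the
node count.

## Key parameters

| parameter | default | rationale |
|---|---|---|
| `fdr_threshold` | 0.05 | conventional ORA significance level, also the node-inclusion rule |
| `min/max_category_size` | 3 / 500 | standard ORA practice: tiny categories are unstable, huge ones uninformative |
| background | union of collections | reproducible when no reference set is stated |
| `bc_bin_width` | 0.1 | distribution reported at 0.1 resolution |
| `include_isolated_genes` | off | network keeps only genes with significant membership |

## Synthetic studies

`SimConfig` defaults describe the curated-study scale this package
targets: a 2000-gene universe; lists of 397 and 148 genes sharing
exactly 58; four collections (50 pathways, 50 molecular functions, 50
cellular components, 20 brain regions) with category sizes uniform on
20–40 and 3 planted categories each; planted categories contain
⌈0.5·58⌉ = 29 shared genes, the rest drawn from the non-shared
universe; non-planted categories are uniform draws. Sampling is without
replacement, the intersection is exact by construction (shared set
first, then disjoint remainders), symbols are synthetic (G000001…), and
each artifact uses its own pseudo-random stream derived from the master
seed so adding a collection never perturbs the lists. The brain-region
collection is smaller because region panels are far smaller than
genome-scale annotation databases.

The planted-hub construction (`plant_hub=True`, off by default) makes
the lexicographically first shared gene a member of every category of
every collection. Its network neighborhood is then a superset of every
other gene's, which guarantees its betweenness is maximal among genes
(any geodesic through another gene maps injectively to one through the
hub), and the smallest-ID tie-break cannot demote it — so it provably
tops the gene ranking in every seed. It is off by default because
guaranteed hub membership makes every category slightly non-null,
inflating the false-discovery proportion a plain recovery benchmark
should measure; the two constructions answer different questions and
are benchmarked separately.

What the generator does **not** emulate: annotation dependence (the GO
DAG, overlapping pathways), realistic category-size distributions,
gene-level ascertainment bias, or any biological identity of the
symbols. Passing recovery benchmarks therefore demonstrates the
statistical machinery under independent random annotation, not
performance on real, correlated databases.

## Reference data

`comorbinet.datasets` bundles the node roster of the published OCD–BD
comorbidity network (62 nodes with types, display names, FDRs and
betweenness values). The gene–category memberships behind its 128 edges
were never published, so `reference_network()` synthesizes a
deterministic membership (cycling categories through the gene roster)
that reproduces the published node and edge counts exactly; individual
edges, and any centrality recomputed from them, are synthetic and are
documented as such. The published per-node betweenness values are kept
as data only — their normalization and underlying edge list are not
recoverable, so they are not recomputation targets.

## Numerical and testing choices

Hypergeometric agreement with the exact-rational oracle is verified
exhaustively over all (n, K, k) for N ≤ 40 and on strided grids at
N ∈ {60, 100, 150, 200} (1e−12 relative); centralities on 50 seeded
bipartite graphs of ≤ 14 nodes (1e−12 absolute). Null calibration uses
2000 uniform random 58-gene queries against 170 null categories,
requiring the p ≤ 0.05 rate to stay at or below 0.05 plus three
standard errors — hypergeometric p-values are discrete and
conservative, so the rate is expected well below nominal (≈ 2.4%
observed). Recovery benchmarks use 100 default-scale seeded studies;
measured recovery is 100% with ≈ 3% false-discovery proportion among
non-planted categories, and the planted hub ranks first in 100/100
planted-hub studies.

## Known limitations

- BH within collection controls FDR per database, not study-wide.
- Brain-region panels from specificity-thresholded expression analyses
  are modeled as ordinary GMT collections under the same hypergeometric
  machinery; tool-specific specificity indices are not reproduced.
- Only membership (gene–category) edges are modeled: no protein–protein
  or gene–gene interactions, weights, or directions.
- The ranked, running-sum flavor of gene-set enrichment (for scored
  lists) is deliberately absent; the pipeline is ORA-only.
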