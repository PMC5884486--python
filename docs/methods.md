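# Methods

## The analysis model

`gwaspathnet` treats a GWAS hit list not as a statistical object but as a
combinatorial one: a set of genomic points to be joined to genes, gene
sets, ontology terms and orthogonal evidence tables. No model is fitted;
every output is a deterministic function of the inputs and the thresholds
below. The value of the analysis lies in which structures survive the
intersections — hub genes, ambiguous multi-gene SNPs, annotation gaps,
and genes supported by several independent evidence types.

### SNP → gene mapping

A SNP links to gene *g* iff `g.start − w ≤ pos ≤ g.end + w` with window
`w = 1000` bp, boundary inclusive ("within 1 kb" read as ≤). The window
is anchored on the gene span, not on UTR coordinates: UTRs are not
present in BED-level input, so span ± 1 kb is a documented approximation
of "1 kb beyond the transcript ends". Multi-mapping is deliberate;
variants inside overlapping genes carry real interpretive ambiguity and
are surfaced as gene-SNP-gene modules (connected components of the
bipartite graph restricted to SNPs with ≥ 2 links). Location classes
refine the link when exon intervals are available (exonic/intronic),
otherwise flanking SNPs resolve to upstream/downstream by strand
(upstream = 5′ side, i.e. right of a minus-strand gene) and in-span SNPs
are `within_gene_unresolved`. Sequence-level consequence prediction is
out of scope.

Percentages are integer, round-half-up, computed in exact integer
arithmetic (`(200·n + d) // (2·d)`). The single exception is the
module-gene disease percentage, which truncates toward zero — the
convention the source tables for that quantity use — and is confined to
`multigene_disease_check`.

### Pathway redundancy and clustering

Curated pathway collections contain near-duplicates. Pruning flags a
pair when Jaccard(gene sets) ≥ `jaccard_min` (default 0.9) **and** the
lowercase name-token overlap (|shared tokens| / |smaller token set|) ≥
`name_overlap_min` (default 0.5); the member with fewer genes is removed
(size ties: lexicographically larger id). Flags are computed once on the
original collection and applied in one pass — no cascade — so the result
is order-independent.

Surviving pathways are rows of a binary membership matrix over a gene
universe. The default universe is the union of pathway genes; the
pipeline passes the SNP-mapped restriction explicitly, because
clustering pathways *in the context of the mapped genes* is the relevant
notion of similarity here (full-content clustering is available via the
`gene_universe` override).

Clustering is agglomerative with Euclidean distance (√ of the Hamming
count on binary rows) and complete linkage, implemented in-package via
the Lance–Williams update `d(i∪j, k) = max(d(i,k), d(j,k))`. Binary rows
make exact distance ties common, so the tie order is pinned: among all
closest pairs, the lexicographically smallest (min representative, max
representative) merges first, a cluster's representative being the
smallest original row index it contains. Squared distances are kept in
integer-exact arithmetic so ties compare exactly. The dendrogram cut at
height *h* unions all merges with height ≤ *h*; the default cut is half
the maximum merge height, an explicit parameter rather than a tuned
constant, because no principled cut exists for arbitrary collections.
Cluster nodes are named `cluster:<smallest member id>` (singletons keep
the pathway id).

### Tripartite network

Nodes are typed snp / gene / pathway_cluster; edges are snp–gene (copied
from the mapping) and gene–cluster (gene in the cluster's union gene set
*and* SNP-linked). Cluster nodes reachable by no SNP-linked gene are
dropped. `validate()` asserts the discipline after every assembly: no
same-type or snp–cluster edges, no isolated gene nodes. Hub degree
counts gene–cluster edges only, threshold inclusive (default ≥ 10).
Components are undirected; the main component is the largest by node
count (ties: more edges, then smallest member id).

### GO comparison

Annotations are restricted to the biological_process namespace and closed
over `is_a` ancestors (closure on by default, with a switch; whether
upstream annotation tools pre-close their output varies, so both
behaviours are available). The namespace root is excluded — it would be
shared trivially by every annotated gene. Group A (genes in no pathway)
vs group B (pathway genes) is pure set algebra with asserted identities:
|exclusive terms| = |A| − |shared|, |exclusive genes| = |A genes| −
|shared-only genes|. Exclusive genes × exclusive terms form a bipartite
network; terms supported by a single gene are flagged as the least
trustworthy (false hit, pleiotropy, or action at a distance). Enrichment
statistics (Z-scores, permutation p-values) are deliberately not
implemented; the comparison uses complete annotation lists.

### Evidence integration

* LD proxy clusters: connected components of the graph with edges where
  r² **strictly** > 0.8 and distance ≤ 500 kb, per population (the
  boundary convention follows the stricter of the two wordings in
  circulation for this filter; both threshold and comparator are
  arguments). Cross-population records are rejected with a warning.
  The independent-signal count of a gene is the number of distinct
  clusters among its SNPs.
* eQTL Venn: a gene belongs to a tissue when any record reaches p ≤ 0.05
  (inclusive). Regions are exact tissue combinations, hence disjoint, and
  region counts sum to the union — asserted on construction.
* Priority table: all genes with ≥ 1 evidence source; `triple` flags
  hub ∧ (any eQTL tissue) ∧ (≥ 1 GxE record); sorted triple-first, then
  disease score descending. A positive disease association means score
  strictly > 0.
* The intergenic filter mode returns all eQTL records for SNPs that map
  to no gene, unfiltered by p — an expression signal is the only
  functional handle such variants have.

## The synthetic-data generator

The generator emulates input *schemas* and the combinatorial structure
the analysis consumes; it does not emulate population genetics. Gene
placement and lengths are uniform, association p-values log-uniform,
eQTL effects Gaussian — chosen for testability, defensible because every
downstream operation is threshold-and-set logic, insensitive to the
shapes of these distributions. It does **not** model realistic LD decay,
allele frequencies, genotypes, or effect sizes, so passing tests
demonstrate correctness of the combinatorial pipeline, not statistical
performance on real data.

Planted structure (all recovered exactly by construction, any seed):

* exactly `n_intergenic` SNPs > 1 kb from every span (sampled from the
  exact complement intervals), `n_multigene_snps` inside planted
  overlapping-gene chains (a module of *m* genes consumes *m* − 1 SNPs),
  the rest inside single regular genes, hub genes covered first;
  inter-unit gaps ≥ 2·window + 100 bp keep windows from bleeding into
  neighbours;
* `n_redundant_pairs` duplicate pathways, each a ≥ 90% subset of its
  source with a shared name token, while all other names are single
  unique tokens — pruning removes exactly the duplicates;
* hub genes in exactly their specified number of pathways and nowhere
  else (they are excluded from all other sampling); every non-hub gene
  joins at most `max_background_memberships` (default 9) pathway units,
  so the ≥ 10 hub threshold separates planted hubs exactly;
* optional cluster families: members share a core gene set and differ
  only in planted hub genes (≤ 3 per pathway), and cores/singleton
  sources are sampled with pairwise-overlap caps, which bounds
  within-family complete-linkage heights at √10 and cross-cluster
  distances at ≥ √18 — a cut at 4.0 recovers families and singletons for
  any seed;
* GO group annotations use only depth-1 children of the BP root, so the
  planted shared/exclusive counts are exact under closure (deeper DAG
  levels exist for closure machinery; MF/CC noise annotations exercise
  the namespace filter);
* eQTL genes are assigned exact tissue combinations; decoy records sit
  strictly above p = 0.05, decoy LD records at r² ≤ 0.8 or beyond the
  distance limit;
* triple-evidence genes are the only genes given all of hub status, eQTL
  records and GxE records.

Randomness: one `SeedSequence(seed)` spawned into fixed-order per-stage
children (genes, SNPs, pathways, GO, evidence), so each generator is
deterministic in isolation and adding configuration fields to one stage
never reshuffles another.

The `realistic_scale()` preset describes a realistic meta-analysis-sized
study: 1,971 SNPs / 716 intergenic on 22 chromosomes; 1,046 genes of
which 368 are pathway-eligible; 460 pathways with 36 redundant
duplicates, 81 cluster families + 36 singletons (117 cluster nodes at
cut 4.0); 27 hub genes; 19 gene-SNP-gene modules over 41 genes, 13 of
them disease-scored (31%); GO counts 1,503 / 1,255 / 248 terms on
196 / 122 / 74 genes; four diabetes-relevant tissues; 3 triple-evidence
genes. It runs end to end in a few seconds on one CPU, which is the
problem size used throughout the test suite.

## Numerical and degenerate-input choices

* Percentages: integer round-half-up everywhere except the truncated
  module-disease figure (above).
* hclust on one row returns an empty dendrogram; cutting it yields one
  singleton cluster. Zero-SNP pipelines skip clustering and emit empty
  tables with success.
* Merge heights are non-decreasing (complete linkage is monotone); the
  cut comparison is ≤.
* Boundary conventions: mapping window inclusive, eQTL p inclusive,
  LD r² strictly greater.
* Ids are compared lexicographically for all deterministic tie-breaks
  (pruning ties, cluster naming, orderings of outputs).

## Known limitations

* The gene window ignores transcript structure; per-transcript windows
  would multi-map more variants.
* The dendrogram cut is a free parameter; cluster counts are
  data-dependent and no cut-selection heuristic is provided.
* Name-token overlap is a crude proxy for "similar names"; curated
  collections with systematic naming (shared boilerplate tokens) would
  need a raised `name_overlap_min`.
* The generator's gene-SNP-gene modules are chains of pairwise-overlapping
  genes; real nested/containment overlap patterns are not produced.
* Evidence integration is id-based; it does not model effect direction,
  colocalization, or tissue sharing beyond set membership.
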