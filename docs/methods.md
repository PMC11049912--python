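# Methods

`pancyan` re-implements, as a tested library, the comparative pan-genomics
workflow used to characterize a bacterial species collection and to mine it
for genes tracking a marker gene cluster: ANI-based species delineation,
ortholog-family construction, core/dispensable/singleton partitioning,
Heap's-law openness, accessory-profile clustering, threshold homolog
screening, anchor-cluster co-occurrence, and functional enrichment. Every
stage is exercised on synthetic pan-genomes with planted ground truth; this
note records the models, the defaults, and the choices that were genuinely
open.

## Pairwise alignment and the identity/coverage conventions

Two aligners underlie everything. `align_global` is an optimal semi-global
alignment (global with free terminal gaps) with affine penalties:
nucleotide +1/−1, gap open −5 / extend −2 (the first gap residue costs the
open penalty), proteins scored with BLOSUM62 and the same gap penalties.
The source workflow delegates pairwise comparison to BLAST and never states
scoring, so these defaults are configurable and logged.

**Identity** is matches over *internal* alignment columns — internal gaps
count in the denominator, terminal overhangs do not. **Coverage** is query
coverage: the fraction of query residues inside the internal region
(subject coverage is also reported). Whether published "coverage"
thresholds mean query or subject coverage is unstated; query coverage is
the implemented default.

Ties between co-optimal alignments resolve by the aligner's canonical
traceback, which is deterministic. On degenerate tiny inputs co-optimal
alignments can differ in identity (never in score); this has no effect at
the sequence lengths of any analysis here.

`align_local_seeded` locates a fragment in a long target: shared k-mers
(k = 15, sampled every `seed_stride` = 4 positions) vote for diagonals, the
best diagonal is realigned in a padded band by edit-distance alignment
(edlib), and the **maximum-scoring contiguous segment** of that alignment
is reported (column scores +1 match, −2 mismatch, −3 gap; random
nucleotide alignments run at ~50–55% matches and therefore score negative,
so segments do not creep into non-homologous flanks). A fragment only
partly homologous to the target thus yields a hit with coverage < 100%,
exactly what the fragment-acceptance rule below needs. With no seeded
diagonal the fragment has no hit.

## ANI and species delineation

Fragment-based ANI follows the ANIb convention: each query contig is cut
into consecutive non-overlapping 1020-bp fragments (trailing remainder
discarded); each fragment is searched in the target; fragments are
accepted at identity ≥ 30% and coverage ≥ 70% of fragment length;
directional ANI is the mean identity of accepted fragments, and the
symmetric ANI of a pair is the mean of the two directions. The cited ANI
tool's internals are not published in the source workflow, so fragment
length and acceptance thresholds are config keys with the conventional
values.

One deliberate guard: a fragment is seeded only when its best diagonal
collects **≥ 2** k-mer hits (`min_seed_hits`). Two unrelated 100-kb genomes
share a handful of 15-mers by chance; a single chance seed would produce an
accepted ~50%-identity edit alignment and a spurious ANI. Requiring two
co-diagonal seeds reproduces the behavior of a local search tool reporting
no significant hit, and unrelated genome pairs come out with undefined
(NaN) ANI.

Species assignment thresholds the symmetric matrix: genomes are connected
when ANI ≥ cutoff and species clusters are the connected components;
singleton components are outliers. The published analysis states both a
96% (Results) and a 95% (Methods) cutoff; the default is 96 and 95 is an
explicit config choice, never silently preferred. The ANI dendrogram is
average-linkage agglomeration on distance = 100 − ANI.

## Ortholog families and the pan-genome partition

Families are single-linkage clusters: an edge joins two proteins whose
semi-global identity reaches the threshold (default 70%), families are
connected components, so every member is within threshold of at least one
other member. Whether the 70% threshold elsewhere means identity over the
aligned region or the full length is unstated; the internal-columns
identity above is used and stated. An optional prefilter skips pairs that
cannot plausibly reach the threshold (only same-length-scale pairs with
length ratio ≥ 0.8, and only when unit-cost edit distance exceeds half the
longer length — a wide margin past anything at 70% identity);
length-discordant pairs are always fully aligned, and tests assert
equality with brute-force components with the prefilter on and off.

A genome "is present" in a family when it carries ≥ 1 member gene;
paralogs do not add matrix columns. Core = present in all genomes,
singleton = present in exactly one, dispensable = in between; with n = 2
genomes the dispensable class is empty by definition and the partition is
refused. Percentages are over the family total, rounded half-up to one
decimal (the printed style of the summaries being reproduced).

Rarefaction adds genomes in uniformly random orders (seeded; an exhaustive
mode walks all G! orders for small G) and records cumulative pan size and
new families per step. Heap's law is fitted as n_new(N) = κ·N^(−α) by
least squares on log–log scale for N ≥ 2 — step 1 is the mean genome size,
not a discovery count, and is excluded (the standard convention for
pan-genome rarefaction fits). α < 1 flags an open pan-genome. Steps with zero mean
discovery carry no log information and are dropped; if fewer than two
informative steps remain the fit is refused rather than guessed.

Accessory-profile clustering removes core columns and applies
average-linkage agglomeration on Jaccard distances between genome presence
vectors (the published figure names neither distance nor linkage; both are
config keys). A genome with an empty accessory vector has no defined
Jaccard distance and is refused with guidance. Dendrograms are exported as
ultrametric Newick: leaf-to-root distance equals the root merge height,
branch length = parent height − child height.

## Homolog screening, neighborhoods, co-occurrence

Marker screening aligns a query protein against every annotated protein
and reports hits at identity ≥ 50% and query coverage ≥ 80% (both config
keys); the presence/absence grid marks a genome when ≥ 1 hit qualifies.
Best hits tie-break by identity, then coverage, then gene id.

`gene_neighborhood` returns up to `window` genes each side on the same
contig in coordinate order; `compare_contexts` scores two neighborhoods by
Jaccard of their family sets and flags "same organization" when the shared
families appear in the same relative order and strand pattern reading
either neighborhood in either direction — assemblies have arbitrary
strandness, so a cluster read on the opposite strand is the same
organization.

Co-occurrence mining: anchor genomes are those containing **all** marker
families (by default a single marker family — the analysis that motivated
this defines "containing" genomes by the marker gene, not by possessing
every cluster gene; the marker set is configurable). A candidate family
must be present in ≥ |anchor| − s_pos anchor genomes and ≤ s_neg
non-anchor genomes; s_pos and s_neg are independent and must be set
explicitly (published phrasing combines them ambiguously). Relaxing either
parameter can only add candidates. Candidate families whose member genes
are immediate gene-order neighbors in some genome are reported as adjacent
pairs.

## Enrichment

One-sided hypergeometric over-representation per category with
Benjamini–Hochberg FDR across tested categories; the upstream annotation
services used for the published analysis do not state their test or
correction, so both choices are declared in every report header. The
background is the full gene set of the analyzed genome(s), matching the
per-strain framing of the original gene-set analysis. Categories carried by
fewer than `min_category_size` (default 2) background genes are skipped as
singleton-category noise.

## The synthetic-data generator

The generator emulates a single-species collection with planted truth:

* **Family structure** — C core families (all genomes), D dispensable
  families on uniformly random subsets of 2..G−1 genomes (no quantitative
  sharing distribution is published; uniform subset size is the stand-in
  and is parameterized), Poisson(S) singletons per genome.
* **Divergence** — every gene and intergenic spacer is an independently
  per-site mutated copy (probability d per site, uniform among the three
  other bases) of an ancestral sequence; no indels by default, so copies
  are positionally alignable and identities/ANI are analytically
  predictable (expected pairwise mismatch 2d(1−d) + (2/3)d²; d = 0.02
  puts within-species ANI near 96%). Spacers are dropped together with
  their gene, so genomes with identical family content stay colinear.
* **Anchor cluster** — 8 contiguous genes `anchorA..H`, `anchorA` upstream
  of and divergently oriented to the co-directional B–H block, mirroring a
  regulator + structural-genes arrangement; present in exactly the anchor
  subset.
* **Planted co-occurrence** — P accessory families confined to the anchor
  subset, designated pairs placed contiguously; F confounders present in
  the anchor subset plus ℓ leaked non-anchor genomes. Singleton insertion
  happens only between layout blocks, never inside the anchor cluster or a
  planted pair.
* **Sequences** — genes are drawn codon-wise from the 61 sense codons
  (length ~Normal(250, 30) codons by default, ≥ 30); proteins are the
  standard-code translations; a mutation creating a stop codon is reverted
  to the ancestral codon so translations stay stop-free. Minus-strand genes
  are reverse-complemented into the contig; the annotation keeps the
  coding-strand sequence.
* **Categories** — one label per gene from a 20-letter COG-like alphabet,
  uniform background; the enriched label's odds are multiplied by the
  enrichment factor (default 6) on a designated target set (default 80
  genes) — comfortably above the regime where the planted category is
  recoverable at q < 0.05.

Defaults (G = 18, 7-genome anchor subset, 2 planted co-occurring genes with
one adjacent pair) mirror the shape of the published species collection at
desk-scale family counts (60 core + 90 dispensable rather than thousands).
What the generator does **not** emulate: rearrangement, recombination, HGT
events, indel-rich divergence, codon-usage bias, multi-contig assemblies,
annotation errors. Passing tests therefore demonstrate correctness of the
algorithms under clean, separable conditions — not robustness to real
assembly and annotation noise.

## Problem sizes and numerics

Test fixtures use a 6-genome simulation (~220 genes); the acceptance
script runs a 10-genome simulation (~760 genes), a 100-permutation
rarefaction, and 60-kb genomes for the outlier experiment — sizes chosen
so the full analysis re-runs in well under a minute while every recovery
check stays discriminating. Percentages round half-up via decimal
arithmetic. The stochastic Heap's check compares the 100-permutation fit
against the fit on the closed-form expected discovery curve
(P(first seen at step N) = C(G−c, N−1)/C(G, N−1) − C(G−c, N)/C(G, N) for a
family with c carriers). Reported α on the default-shaped simulations runs
≈ 0.78–0.90 (open); the published real-data value (≈ 0.73) requires the
real genome set, which is out of scope here.

## Known limitations

* The seeded ANI aligner is a banded heuristic; at divergences beyond
  ~25% seeding density, not the 30% identity floor, is what rejects
  fragments.
* Single-linkage clustering inherits its usual chaining risk; the 70%
  threshold with ~25% between-family identity in the simulations keeps
  families separable, which real paralog-rich proteomes need not do.
* The co-occurrence report is presence/absence only; it does not model
  phylogenetic non-independence of genomes.
* Enrichment treats category labels as given and flat (no GO-graph
  propagation or pathway mapping).
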