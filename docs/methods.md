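# Methods

This note documents the models and procedures the package implements, the
parameters that matter, and what the synthetic-data generator does and does
not emulate.

## Phylogenetic timing by reconciliation

Gene trees are consumed rooted, with species-tagged leaves (sidecar TSV map or
`geneID_speciesID` leaf names), and reconciled against a rooted species tree
with uniquely named internal taxa by standard LCA mapping: each internal node
maps to the species-tree LCA of its descendant species and is labelled a
**duplication** iff at least one child maps to the same species-tree node,
otherwise a **speciation**. The mapped taxon of a duplication is its
*phylogenetic timing*. No re-rooting and no tree inference are performed —
tree building is upstream of this package.

**Species-intersection support (SIS).** For a duplication with child-clade
species sets `L` and `R`, `SIS = |L ∩ R| / min(|L|, |R|)`. SIS = 0
duplications (no shared species between the two sides) are more
parsimoniously local topology artifacts and are dropped by the default filter
(`sis_min = 0`, strict `>`). The intersection/union variant is available via
`sis_mode="union"`. Multifurcations are resolved to an arbitrary ladder whose
inserted nodes carry SIS = 0, so resolution can never create a supported
duplication.

**Two-wave partition.** Among duplications of one tree timed to the WGD
taxon, *round 1* nodes have no like-timed duplication ancestor; every other
like-timed node is *round 2*. This is a purely topological definition and
needs no branch lengths.

## Retention estimation

With `O` ohnolog-mapped focal-species genes, `N` ancestral pre-WGD gene
lineages, `T` extra copies created by post-WGD duplications inside the ohnolog
set, and `F_small`/`F_large` two alternative counts of genes outside ohnolog
families:

```
overall = 100 · O / (4N)
upper   = 100 · (O − T) / (4N + F_small)
lower   = 100 · (O − T) / (4N + F_large)
```

`N` is computed by projecting each focal gene root-ward to its topmost
ancestor still mapped inside the WGD taxon's clade and counting distinct
projection targets. `T` merges ohnolog genes whose pairwise MRCA is a
supported duplication timed strictly younger than the WGD and counts
`genes − lineages` — one inflating copy per younger duplication node. A gene
descending from both a WGD-timed and a younger duplication therefore counts
once in `O` and once (as part of its collapsed lineage) toward `T`.

## Paralogon (multiplicon) detection

Anchors are positioned paralog pairs on ordinal gene coordinates (0-based,
half-open segments); the gap parameter counts intervening *genes*, matching
how synteny tools parameterise ancient WGD footprints. Detection is iterated
best-chain extraction per chromosome pair: an `O(m²)` dynamic program finds
the longest strictly monotone chain (same or inverted orientation) whose
consecutive anchors are separated by at most `max_gap = 30` intervening genes
on both segments; chains need `min_anchors = 5`. Tandem-array anchors
(pairs adjacent on one chromosome) are collapsed before chaining to avoid
self-synteny.

Two filters follow:

* **Significance.** For a chain of `k` of the pair's `m` anchors with observed
  index steps `(Δx_i, Δy_i)` on chromosomes of `N1`, `N2` genes, the expected
  number of equally tight chains under uniform anchor scatter is bounded by
  `E = C(m, k) · 2 · Π_i (Δx_i/N1)(Δy_i/N2)`; the chain is kept when
  `min(1, E) ≤ prob_cutoff` (default `1e-5`). This deliberately simple
  expected-count bound replaces the full generalised homology matrix
  probability model of dedicated synteny software; it is a stated stand-in,
  isolated in one function, and swappable.
* **Quality (default 0.8).** The fraction of the chromosome pair's anchors
  inside the two segment windows that are *consistent* with the chain —
  insertable between neighbouring chain anchors under non-strict
  monotonicity. Strict chain membership is the wrong denominator semantics
  here: multi-copy families produce tied coordinates that no strictly
  monotone chain can absorb, yet such anchors plainly lie on the diagonal.

Genome coverage is the unioned fraction of ordinal positions inside at least
one detected segment, per chromosome and overall.

## Expression measures

The atlas is a genes × tissues matrix of non-negative average-difference (AD)
microarray signals. Multiple probes per gene are arithmetic-averaged *before*
anything else; genes with cross-tissue mean `A < 50` or `A > 999` are then
excluded (flagged with reasons); finally `PEM(g, t) = log10(S/A)`. Cells with
`S = 0` get no PEM value (flagged NaN) rather than a log of zero. A gene
counts as expressed in a tissue when `S ≥ 200` (boundary included; the flag is
a documented choice), breadth is the percentage of tissues above that cutoff,
and `PEM_MAX` the per-gene maximum. PEM is scale-invariant: multiplying a
profile by a constant cancels through `A`.

The taxon × tissue signature matrix averages PEM over genes whose creating
duplication is timed to each taxon; rows and columns are ordered by
average-linkage hierarchical clustering on Euclidean distance with
deterministic (label-order) tie-breaking.

Paralog expression divergence supports Pearson, Spearman, Kendall, Manhattan
and absolute breadth difference ("simple difference in breadth" is
implemented as an absolute difference — the direction is not meaningful for
unordered pairs). A pair's age class is the mapped taxon of its most recent
common duplication node; summaries (median, quartiles) are reported per age
class ordered oldest → youngest. Correlations of constant profiles are
undefined: such pairs are flagged and excluded from summaries.

## Signalling network statistics

Networks are signed and partially directed: undirected *scaffold* (physical)
edges, directed *positive*/*negative* regulatory edges; parallel typed edges
between one node pair are allowed and each counts once toward degree.
Betweenness is Brandes' algorithm (networkx), normalised to [0, 1], computed
on the undirected projection by default and on the directed graph via a flag
for regulatory-only analyses.

Permutation significance resamples node labels without replacement; sampled
p-values use the `(k+1)/(n+1)` estimator (never exactly zero), and an
exhaustive mode enumerates all same-size subsets on small inputs.

**Pair conservation.** For a paralogous pair, edges are matched on
(third node, direction relative to the pair member, polarity); scaffold edges
match undirected. Both members of a matched edge pair count toward the shared
count; the conserved fraction is shared/total over the pair's incident edges.
Self-loops are ignored, and the pair's own bridging edges are excluded from
both the shared and total counts (they are duplication novelties, not
inherited interactions). Two pooled summaries are reported, as both are
informative and differ under heterogeneous degrees: Σshared/Σtotal and the
mean of per-pair fractions. Shared regulatory edges split into CIE (third
node → both paralogs) and COE (both paralogs → third node) per polarity;
scaffold matches are excluded from that classification. The random-pair null
reports the expected shared-edge fraction and the fraction of pairs with ≥ 1
shared edge over uniformly sampled node pairs (exhaustive on small graphs).

## Triads and expression fates

A triad is a unique outgroup ortholog plus a focal-species paralog pair. The
outgroup gene qualifies when its MRCA with the pair is a speciation node and
all supporting nodes (that speciation and the pair's duplication MRCA) carry
bootstrap strictly above 0.75 where recorded; families with zero or multiple
candidate orthologs are skipped with counted reasons. Preferential brain
expression (PBE) is brain signal strictly above the gene's own cross-tissue
mean (the mean includes brain); the same strictness applies to all three
genes, and the ancestral gene is judged against its own species' atlas.
Cross-species tissue matching is restricted to a declared analogous-tissue
map, brain-only by default. The six configurations
(`b:b&b`, `b:nb&b`, `b:nb&nb`, `nb:b&b`, `nb:nb&b`, `nb:nb&nb`; paralog order
canonicalised) partition all triads; summary ratios (conservation/sub,
conservation/neo, sub/neo) are flagged undefined on zero denominators.

## Enrichment

Plain hypergeometric tails: over-representation `P(X ≥ k)`, under
`P(X ≤ k)`, with optional Benjamini–Hochberg adjustment; annotation gene sets
are intersected with the universe first. Hierarchy-aware (ontology-graph
conditional) correction is explicitly out of scope — terms are tested flat.
Positional clustering uses chromosomes and, by default, half-overlapping
25-gene windows as terms; the window size is exposed because no canonical
value exists, and results report it.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed once:

* **Species ladder** — ten nested taxa (Eukaryota → Catarrhini) each with one
  extant side species, terminating in the focal species; ages are measured in
  ladder steps because the analyses need only relative timing.
* **Families** (`n_families = 200`) evolve by per-branch tandem birth
  (`per_branch_dup_rate = 0.02`), optional loss (`loss_rate = 0` by default;
  real post-WGD loss rates are lineage-specific and unknown, so loss is a free
  parameter), and a two-round WGD on the Vertebrata stem with per-round
  retention `0.15` — the ~10–15%-per-round regime that makes the overall
  ohnolog yield realistic. Round 1 duplicates each lineage and keeps the new
  copy with probability `retention_round1`; round 2 repeats this on every
  surviving copy. All randomness derives from one seed through per-family
  substreams; identical config + seed gives bitwise-identical outputs.
* **Layout** — ohnolog track *t* of each family goes to chromosome
  `t mod n_chromosomes` in family order, producing collinear blocks on
  partner chromosomes; tandem duplicates sit adjacent to their previous copy
  with probability `tandem_fraction = 0.7`; single-copy families rotate
  across chromosomes as filler. This concentrates ohnologs on a few
  chromosome tracks — unlike real genomes, where rearrangements spread
  paralogons — so positional-enrichment results on synthetic ohnologs are a
  generator artifact, not a biological signal.
* **Expression** — each family draws an ancestral per-tissue log-signal from
  Normal(5.3, 1.0) (median AD ≈ 200, the expressed cutoff); along every
  gene-tree edge of length `dt` ladder steps each tissue drifts independently
  by Normal(0, `divergence_rate`² · dt) in log space
  (`divergence_rate = 0.25`). This is the simplest model producing the
  monotone decay of paralog expression similarity with age; it has no
  tissue-tissue correlation structure, no probe-level noise and no
  normalisation artifacts, so passing tests demonstrate the *measures*, not
  robustness to microarray pathologies. `wgd_tissue_boost` optionally
  multiplies the brain signal of WGD descendants to emulate a
  nervous-tissue-skewed retention signature.
* **Network** — an Erdős–Rényi-style ancestral network over families (mean
  degree 6.2; polarity mix positive/negative/scaffold = 0.475/0.146/0.379,
  the edge-type composition of curated human signalling maps).
  Duplication-divergence inheritance: an ancestral edge materialises as every
  descendant combination, each retained with probability
  `edge_inheritance_q = 0.7` (probability 1 between two single-copy
  families), preserving polarity and direction; duplicates gain
  Poisson(`edge_gain_rate = 0.5`) novel edges that never target the
  co-duplicate (bridging is controlled solely by `bridging_prob = 0.107`,
  matching the observed bridged-pair rate of ~48/450). Under this model the
  pooled conserved-edge ratio has expectation exactly `q`; the per-pair mean
  fraction is a ratio estimator with an O(1/degree) downward bias (~0.04 at
  mean degree 6, negligible by degree ≥ 12), which is why convergence checks
  use larger neighbourhoods.

## Numerical and degenerate-input choices

Zero-mean expression rows are excluded, never divided. Retention with zero
ancestral genes, empty universes/gene sets, unknown taxa/tissues and malformed
networks raise typed errors (`ConfigurationError`, `InputError`,
`ComputationError`). Chain extraction breaks ties deterministically (input
order after a fixed sort); hierarchical-clustering orderings are deterministic
by pre-sorting labels. Empirical p-values are never zero by construction.
Problem sizes in the test-suite and acceptance script (2,000 families for
recovery checks, 350–500 families elsewhere, 20 planted blocks) were chosen as
the smallest sizes at which the 3σ statistical checks are stable.

## Known limitations

* Tree building, re-rooting and bootstrap computation are out of scope; trees
  are trusted as given.
* The multiplicon significance filter is an expected-count bound, not the
  generalised homology matrix model; only pairwise segments (no level-3+
  profiles) are detected.
* Enrichment is flat (no ontology-graph correction) and positional windows
  are a parameter, not an inference.
* The generator does not simulate sequences, branch lengths, karyotype
  rearrangements, correlated tissue profiles, or network motif structure
  beyond what duplication-divergence induces.
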