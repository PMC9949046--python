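# Methods

This note records the models, conventions and numerical choices behind
`rdkg`, in the order the pipeline runs them, together with what the
synthetic benchmark does and does not demonstrate.

## Graph model

The knowledge graph is a set of typed nodes (disease, gene, phenotype,
go_term, hpo_term, small_molecule, pathway) and labeled triples
(source, relation, target).  Triples are stored directed as read but
every traversal is undirected: random walks must move freely up and down
the ontology layers (a disease–phenotype–HPO class–phenotype–disease
path is the canonical length-4 bridge between diseases).  Duplicate
triples collapse; distinct relation labels between the same node pair
are all kept, because each label is a distinct walk token.  Diseases
attach only to genes (`has_gene`) and phenotypes (`has_phenotype`); the
assembly routine cannot produce a direct disease–disease edge.

Ontologies carry the *asserted* `is_a` hierarchy only.  No description-
logic reasoning is performed: every downstream computation (annotation
pruning, information content, most-informative common ancestors) needs
ancestor/descendant relations and nothing else, and the asserted
hierarchy plus transitive closure supplies those.  Whether
reasoner-inferred subclass edges would change walk behavior is untested
here and an open question.

Annotation pruning removes, per entity, every annotated term that is a
proper `is_a` ancestor of another annotated term of the same entity
(keep *kinase binding*, drop *protein binding*).  The operation is
idempotent.  Identifier harmonization applies two-column mapping tables
transitively until fixpoint; unmapped ids are kept verbatim (so lossless
on synthetic data) and counted in a report, one-to-many mappings fan the
edge out to all canonical ids, and circular chains raise an error.

## Balanced walks

`W` walks of `L` node-steps start at every disease.  At any visit to a
disease node having both gene and phenotype neighbors — not only the
start node; a disease reached mid-walk poses the same imbalance problem —
the walker picks the gene or phenotype branch with probability ½, then a
uniform neighbor within the branch.  All other nodes step uniformly over
all (relation, neighbor) entries.  Dead ends truncate the walk; there is
no restart or teleport.  Walk length counts node-steps, so a complete
walk has `2L + 1` tokens with relation labels interleaved.  Each disease
draws from its own stream seeded by `hash(seed, disease-id)`, making the
corpus independent of generation order and reproducible in parallel.

Defaults (`WalkParams`): W = 250, L = 250 — the final analysis settings.
Tests and the acceptance script run scaled-down studies (typically
W = L = 50 on 240 diseases, or W = 10–20 on 30 diseases), which already
saturate recovery on the synthetic benchmark; the sensitivity scan shows
silhouette improving with W and plateauing, so the full-size settings are
a safety margin, not a requirement, at synthetic scale.

## Skip-gram embedding

The trainer is an explicit-matrix skip-gram: symmetric windowed
co-occurrence counts over the corpus (window `c` in tokens, edge-label
tokens count), converted to shifted positive PMI,
`max(0, pmi − ln k)` with `k` the `negative` parameter (default 1, i.e.
plain PPMI), then a truncated SVD; the vector of token *w* is
`U_w · √σ`.  This is the matrix that skip-gram with negative sampling
implicitly factorizes, and it has two properties the pipeline needs:
bit-for-bit determinism under a fixed seed, and single-threaded
execution, so cluster labels are exactly reproducible.  There is no
epoch count — the factorization is closed-form rather than iterative.
Defaults: dimension 32, window 20, min_count 0 (rare diseases are never
dropped).  If the requested dimension exceeds the achievable rank, the
trailing columns are zero.

Dimension guidance: `suggest_dimension` returns the rounded (half-up)
fourth root of the corpus vocabulary size, where vocabulary counts unique
tokens — unique nodes plus unique edge labels actually traversed.  The
PCA explained-variance profile of a trained embedding shows whether the
width can be reduced (a sharp drop-off) or is saturated (flat).

## Clustering and K selection

k-means uses k-means++ initialization with `n_init = 10` restarts
(best inertia kept) and Euclidean distance throughout.  Internal metrics
are the textbook silhouette (samples in singleton clusters contribute 0),
Davies–Bouldin and Calinski–Harabasz; degenerate inputs (a single
cluster, or all points identical) raise instead of returning misleading
numbers.

K is selected by the offline kneedle detector on the inertia-vs-K curve:
min–max normalize both axes, compute the gap between the chord joining
the endpoints and the normalized curve, and return the K at the maximal
gap if it exceeds `S/(n−1)` with sensitivity `S = 1`; ties break toward
the smallest K (parsimony).  A perfectly linear or flat curve has no
knee and returns none, in which case the pipeline falls back to the
silhouette-maximizing K.  Because finite `n_init` can leave small local
increases in the inertia curve, the pipeline applies a running-minimum
envelope before the knee search, which requires a nonincreasing input.
The default scan range is K ∈ [2, 100], clipped to the sample size.

## Permutation gene enrichment

For each (gene, cluster) pair with at least one observed annotation,
the observed count is the number of the cluster's diseases annotated to
the gene.  The null permutes the disease→cluster assignment B times
(annotations fixed) and

    p = (1 + #{b : count_b ≥ observed}) / (B + 1).

The `≥` comparison with the add-one correction keeps p strictly positive
and valid under ties, which a strict `>` without correction would not.
Benjamini–Hochberg q-values are computed over the family of all tested
pairs.  Default B = 500,000 (final analysis); tests use B = 10,000.
Permutations are processed in batches of 256 as one sparse–dense matrix
product each; the RNG stream and the results are identical to the
one-at-a-time loop.

The p-values are *discrete*: their support is the attainable tail
probabilities of hypergeometric-type counts.  With few annotations per
gene the atoms are large and the p-values markedly conservative.  The
calibration benchmark (`generate_null_annotations`) therefore simulates
large annotation sets — 12,000 diseases, 5 clusters of unequal expected
share (12–28%), 700 genes annotated to 5,000–7,000 diseases each — so
the null count standard deviation is ≈ 18–25 and the uniformity
diagnostics (rejection rate at 0.05, KS band) apply as intended.
Unequal cluster sizes also mirror real cluster-size distributions.

## tf-idf walk features

Every occurrence of a labeled disease token in the corpus contributes
the tokens within `window` positions on either side (truncated at walk
ends, excluding the occurrence itself) to its cluster's term counts;
windows of nearby occurrences may overlap and then double-count, the
simplest reading of per-occurrence windows.  `df(feature)` is the number
of clusters where the feature appears at all;
`tfidf = tf · ln(N_clusters / df)` with natural log and no smoothing
(df ≥ 1 whenever tf > 0, so the ratio is always defined).  Percentiles
come from the pooled empirical CDF of all tfidf values.  The window
defaults to the embedding context size.  Feature types are looked up in
the graph's node-type map; relation labels type as `relation`.

## Semantic-similarity validation

Intrinsic information content of a term in the validation hierarchy:

    IC(c) = −ln( (|leaves(c)| / |subsumers(c)| + 1) / (max_leaves + 1) )

with leaves(c) the leaf descendants of c (c itself if a leaf),
subsumers(c) the ancestors of c including c, and max_leaves the
hierarchy's total leaf count.  IC is 0 at the root of a tree and never
decreases down an `is_a` chain.  The pairwise measure is the Lin form,
`2·IC(MICA)/(IC(a)+IC(b))` with MICA the common ancestor of maximal IC —
bounded in [0, 1] and the standard companion to intrinsic IC; a
Jiang–Conrath-style distance would be a drop-in alternative.  Natural
log throughout.

Cluster validation compares the mean pairwise similarity within each
cluster against `n_sets = 100` random disease sets whose size defaults
to the rounded mean cluster size; diseases absent from the hierarchy are
dropped with a logged count and clusters left with fewer than two
resolvable diseases are reported missing, never as zero.  The test is a
one-sample Student's t of the cluster means against the null-set mean
(two-sided, n_clusters − 1 df).  The wording of such tests is ambiguous
between this t-form and a z-form scaled by the null-sample standard
deviation; the z-form is available via `use_null_variance=True`.  If the
cluster means have zero variance and sit exactly on the null mean the
test returns t = 0, p = 1; zero variance anywhere else is an error.

## Synthetic benchmark

`SyntheticConfig` defaults define the study conditions: 8 clusters × 30
diseases, 8 genes and 12 phenotypes per module (phenotype annotations
deliberately outnumber gene annotations, as in real disease-annotation
resources — this is what makes the balanced walk matter), annotation
noise 0, GO/HPO-like complete trees of depth 3 and branching 3 with each
gene/phenotype attached to two random leaves, within-module pathway
edges with probability 0.3, and 50 small molecules whose target counts
follow a Zipf(2) draw, echoing the heavy-tailed degree distribution of
real molecular networks.  Noise is *rewiring* — an annotation is
redirected to a random out-of-module target with the given probability —
so annotation counts stay fixed and power analyses are clean.  The
validation hierarchy places one subtree per planted cluster under a
shared root and nests two seeded random-size subgroups inside every
cluster of ≥ 4 diseases, echoing the irregular class depth of real
disease ontologies (and giving the within-cluster means the variance a
t-test needs even at perfect recovery).

What the benchmark emulates: block-structured annotations, type
imbalance, ontology bridging, heavy-tailed ligand degrees, external
validation semantics aligned with (but structurally separate from) the
planted clusters.  What it does not: realistic disease nomenclature,
annotation sparsity and publication bias, cross-ontology axioms,
overlapping or hierarchical disease groups, and real identifier
namespaces.  Passing tests therefore demonstrate that the pipeline
recovers planted structure under controlled noise — not that real-data
clusters at full scale would reach any particular quality.

## Problem sizes

Default test/acceptance studies are scaled for a single CPU: recovery
runs use 240 diseases (8 × 30), W = L = 50, dimension 16, K scanned over
[2, 16], B = 10,000 permutations, 100 null sets; the calibration study
is 12,000 diseases × 700 genes at B = 10,000.  These sizes saturate the
synthetic benchmark (ARI 1.0, all module genes recovered) and complete
in seconds to about a minute per stage.

## Known limitations

* The asserted-hierarchy simplification ignores reasoner-inferred
  subclass edges; on ontologies with heavy cross-classification the walk
  context would differ.
* Explicit-matrix skip-gram differs from SGD word2vec in optimization
  path (not in the factorized objective); absolute embedding coordinates
  are not comparable between the two, though downstream cluster
  structure is.
* Permutation p-values are conservative when annotation counts are
  small; q-value thresholds inherit that conservativeness.
* kneedle assumes a convex, decreasing inertia curve; multi-knee or
  noisy curves may select a local feature (mitigated by the monotone
  envelope and the silhouette fallback).
* The one-sample t-test treats cluster means as exchangeable; clusters
  of very different sizes violate equal-variance tacitly (the z-form is
  offered, but neither models size heterogeneity).
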