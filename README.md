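# rdkg — clustering rare diseases in an ontology-enriched knowledge graph

Rare diseases are individually rare but collectively common, spread across
thousands of conditions that mostly lack approved therapies.  Groups of
rare diseases that share causal genes, phenotypes or pathways are natural
units for drug repurposing and platform-based therapeutic development —
but finding those groups requires integrating annotation sources that no
single similarity score covers.  `rdkg` implements a knowledge-graph
approach for researchers working on rare-disease informatics: diseases,
genes, phenotypes, GO/HPO ontology terms, pathways and small molecules are
assembled into one heterogeneous graph, disease nodes are embedded by
random walks + skip-gram, and the embedding is clustered and then
validated against external semantics and gene-enrichment statistics.

## Method

1. **Graph assembly** (`rdkg.graph`, `rdkg.ontology`): OBO ontologies
   (asserted `is_a` hierarchy), disease→gene / disease→phenotype
   annotation tables, interaction edge lists and ligand-activity tables
   are merged into a typed graph.  Redundant annotations are pruned (a
   gene annotated to both *protein binding* and its subclass *kinase
   binding* keeps only the subclass), over-connecting subtrees (e.g.
   HPO's mode-of-inheritance branch) can be removed, and identifiers are
   harmonized through mapping tables.
2. **Balanced random walks** (`rdkg.walks`): walks start at every disease.
   Because diseases typically carry many more phenotype than gene
   annotations, a step from a disease node first chooses the *gene branch*
   or the *phenotype branch* with probability ½ each, then a uniform
   neighbor within the branch; all other nodes step uniformly.  Edge
   relation labels are emitted as tokens between node tokens.
3. **Skip-gram embedding** (`rdkg.embed`): the walk corpus is factorized
   with an explicit-matrix skip-gram — windowed co-occurrence counts →
   shifted positive PMI → truncated SVD, the matrix that skip-gram with
   negative sampling implicitly factorizes.  Embedding width can be guided
   by the fourth-root-of-vocabulary heuristic and the PCA
   explained-variance profile.
4. **Clustering** (`rdkg.cluster`): k-means over the disease vectors; the
   number of clusters K is the knee of the inertia-vs-K curve found by the
   kneedle detector (max gap below the chord after min–max normalization).
   Silhouette, Davies–Bouldin and Calinski–Harabasz support sensitivity
   scans over walk/embedding hyperparameters.
5. **Validation** (`rdkg.enrich`, `rdkg.semsim`):
   * permutation gene enrichment — for each (gene, cluster) pair the
     disease→cluster assignment is permuted B times with annotations
     fixed; `p = (1 + #{count_b ≥ observed}) / (B + 1)`, with
     Benjamini–Hochberg FDR over the tested pairs;
   * tf-idf of walk-window features per cluster (cluster = document,
     `idf = ln(N_clusters / df)`), summarized at percentile cutoffs;
   * intrinsic information-content similarity on an external disease
     hierarchy: `IC(c) = −ln((|leaves(c)|/|subsumers(c)| + 1)/(max_leaves + 1))`,
     pairwise similarity in the Lin form
     `2·IC(MICA)/(IC(a)+IC(b))`, with a one-sample t-test of
     within-cluster means against random disease sets of matched size;
   * per-cluster druggability summaries from target-development-level
     (TDL) labels and approved-drug connections.

A synthetic-data module (`rdkg.synth`) generates graphs with *planted*
cluster structure — module-private gene/phenotype sets, tunable rewiring
noise, heavy-tailed small-molecule degrees and a cluster-aligned
validation hierarchy — so every stage is testable against known ground
truth, without downloads.

## Worked example

```bash
python examples/07_full_pipeline.py
```

runs the whole pipeline on a synthetic study with 5 planted clusters of
20 diseases and prints:

```
selected K: 5 (planted: 5)
adjusted Rand index vs planted labels: 1.000
genes enriched at q < 0.01: 40
semantic-similarity p-value: 5.74e-09
```

The kneedle-selected K matches the planted cluster count, the adjusted
Rand index of 1.0 means the partition was recovered exactly, all 40
module genes reach significance, and clustered diseases are far more
semantically similar than random sets.  `examples/01…06` walk through the
stages one at a time (graph statistics, walk balancing, K selection,
enrichment, tf-idf features, semantic validation), each printing the
numbers it computes and what they mean.

Real data runs use `rdkg.pipeline.RealInputs` with paths to OBO files,
annotation TSVs, edge lists and mapping tables; artifacts of every stage
are plain files (TSV/CSV/JSON/OBO/gzipped text) written under the output
directory, and a rerun resumes from whatever already exists.

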