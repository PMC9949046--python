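"""The whole pipeline, end to end, on a synthetic study.

Graph -> balanced walks -> skip-gram embedding -> k-means with kneedle
selection -> permutation enrichment -> semantic-similarity validation,
with every stage's artifacts written as plain files under ./scratch/run.
Rerunning reuses existing artifacts (delete a file to recompute it).
"""

from pathlib import Path

from rdkg import (
    EmbedParams,
    PipelineConfig,
    SyntheticConfig,
    WalkParams,
    end_to_end_recovery,
)

config = PipelineConfig(
    synthetic=SyntheticConfig(n_clusters=5, diseases_per_cluster=20, seed=21),
    walk=WalkParams(walks_per_disease=25, walk_length=25),
    embed=EmbedParams(dimension=16, window=10),
    k_min=2,
    k_max=10,
    permutations=2_000,
    n_sets=50,
    seed=22,
)
outdir = Path("scratch/run")
results = end_to_end_recovery(config, outdir)

print(f"artifacts under {outdir}/:")
for path in sorted(outdir.iterdir()):
    print(f"  {path.name}")
print(f"\nselected K: {results['selected_k']} (planted: 5)")
print(f"adjusted Rand index vs planted labels: {results['ari']:.3f}")
print(f"genes enriched at q < {config.fdr}: {results['n_enriched_genes']}")
print(f"semantic-similarity p-value: {results['semsim']['p_value']:.2e}")
# ARI 1.0 means the planted partition was recovered exactly; the
# enrichment and similarity numbers replicate the validation pattern on
# known ground truth.
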