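"""End-to-end orchestration: graph -> walks -> embedding -> clustering ->
enrichment -> semantic-similarity validation.

The pipeline runs in synthetic mode (a :class:`~rdkg.synth.SyntheticConfig`
generates every input, including the validation ontology and ground truth)
or in real mode (paths to OBO ontologies, annotation TSVs, edge lists and
mapping tables).  Every stage writes plain-text artifacts (TSV/CSV/JSON/
OBO/gzip text) under the output directory, so any stage is inspectable and
replaceable; a rerun with the same configuration reuses artifacts that
already exist and re-executes only missing stages.

One global seed governs the run: each stage draws its own seed derived by
hashing the stage name with the global seed, so stages are independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .cluster import select_k
from .embed import EmbeddingMatrix, EmbedParams, train_embedding
from .enrich import (
    permutation_enrichment,
    summarize_by_percentile,
    summarize_drug_connections,
    tfidf_features,
)
from .graph import (
    AnnotationSet,
    assemble_graph,
    harmonize_ids,
    read_kg,
    write_kg,
)
from .ontology import load_obo, prune_redundant_annotations, prune_subtree, write_obo
from .semsim import cluster_semsim, null_semsim, semsim_t_test
from .synth import (
    SyntheticConfig,
    generate_activity_table,
    generate_kg,
    generate_validation_ontology,
    read_ground_truth,
    write_ground_truth,
)
from .walks import WalkParams, derive_seed, generate_walks, read_corpus, write_corpus

__all__ = ["RealInputs", "PipelineConfig", "run_all", "end_to_end_recovery"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RealInputs:
    """Paths to on-disk inputs for a real-data run."""

    gene_annotations: Path  # TSV: disease_id, gene_id
    pheno_annotations: Path  # TSV: disease_id, hpo_id
    go_obo: Path
    hpo_obo: Path
    validation_obo: Path  # ORDO-like hierarchy over the disease ids
    interaction_edges: tuple[Path, ...] = ()
    activity_table: Path | None = None  # TSV: target, ligand, is_approved_drug, tdl
    mapping_tables: tuple[Path, ...] = ()
    gene_go_annotations: Path | None = None  # TSV: gene_id, go_id
    prune_terms: tuple[str, ...] = ("HP:0000005",)


@dataclass(frozen=True)
class PipelineConfig:
    """Full run configuration.  Defaults are the final analysis settings:
    250 walks of length 250, context window 20, embedding dimension 32,
    500,000 permutations, FDR 0.01, 100 null sets of the mean cluster size."""

    synthetic: SyntheticConfig | None = None
    real: RealInputs | None = None
    walk: WalkParams = field(default_factory=WalkParams)
    embed: EmbedParams = field(default_factory=EmbedParams)
    k_min: int = 2
    k_max: int = 100
    n_init: int = 10
    permutations: int = 500_000
    fdr: float = 0.01
    n_sets: int = 100
    set_size: int | None = None  # default: round(mean cluster size)
    percentile_thresholds: tuple[float, ...] = (50.0, 75.0, 90.0, 95.0, 99.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.real is None):
            raise ValueError("exactly one of synthetic / real inputs must be set")
        if self.synthetic is not None and self.synthetic.n_clusters < 2:
            raise ValueError("synthetic mode needs at least 2 planted clusters")
        if self.real is not None:
            for f in dataclasses.fields(RealInputs):
                value = getattr(self.real, f.name)
                paths = value if isinstance(value, tuple) else [value]
                for p in paths:
                    if isinstance(p, (str, Path)) and not Path(p).exists():
                        raise FileNotFoundError(f"missing input: {p}")


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    return derive_seed(config.seed, stage) % (2**31)


def _read_tsv_pairs(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    key, val = df.columns[:2]
    out: dict[str, set[str]] = {}
    for k, v in zip(df[key], df[val]):
        out.setdefault(k, set()).add(v)
    return out


def _build_graph_stage(config: PipelineConfig, out: Path) -> None:
    if config.synthetic is not None:
        kg, truth = generate_kg(config.synthetic)
        write_ground_truth(truth, out / "ground_truth.csv")
        write_obo(
            generate_validation_ontology(truth, seed=_stage_seed(config, "validation")),
            out / "validation.obo",
        )
        activity = generate_activity_table(kg, seed=_stage_seed(config, "activity"))
        activity.to_csv(out / "activity.tsv", sep="\t", index=False)
    else:
        real = config.real
        go = load_obo(real.go_obo)
        hpo = load_obo(real.hpo_obo)
        for term in real.prune_terms:
            if term in hpo:
                hpo = prune_subtree(hpo, term)
            elif term in go:
                go = prune_subtree(go, term)
        annotations = AnnotationSet(
            disease_to_genes=_read_tsv_pairs(real.gene_annotations),
            disease_to_phenotypes=_read_tsv_pairs(real.pheno_annotations),
        )
        gene_go = (
            _read_tsv_pairs(real.gene_go_annotations)
            if real.gene_go_annotations
            else {}
        )
        gene_go = prune_redundant_annotations(gene_go, go) if gene_go else {}
        pheno_terms = {
            p: ({p} if p in hpo else set())
            for phenos in annotations.disease_to_phenotypes.values()
            for p in phenos
        }
        pheno_terms = {p: ts for p, ts in pheno_terms.items() if ts}
        interactions = None
        if real.interaction_edges:
            frames = [
                pd.read_csv(p, sep="\t", dtype=str) for p in real.interaction_edges
            ]
            interactions = pd.concat(frames, ignore_index=True)
            if real.mapping_tables:
                mappings = [
                    pd.read_csv(p, sep="\t", dtype=str) for p in real.mapping_tables
                ]
                interactions, report = harmonize_ids(interactions, mappings)
                (out / "harmonization.json").write_text(json.dumps(report, indent=2))
        activity_edges = None
        if real.activity_table:
            activity = pd.read_csv(real.activity_table, sep="\t")
            activity.to_csv(out / "activity.tsv", sep="\t", index=False)
            activity_edges = activity[["ligand", "target"]].astype(str)
        kg = assemble_graph(
            annotations,
            go,
            hpo,
            gene_go_annotations=gene_go,
            interaction_edges=interactions,
            activity_edges=activity_edges,
            pheno_term_annotations=pheno_terms,
        )
        import shutil

        shutil.copy(real.validation_obo, out / "validation.obo")
    write_kg(kg, out / "nodes.tsv", out / "edges.tsv")


def run_all(config: PipelineConfig, outdir) -> dict:
    """Execute every stage, resuming from existing artifacts.

    Returns a dict with the in-memory results of the final stages (selected
    K, labels, enrichment table, semantic-similarity report) plus the paths
    of all artifacts.  A stage failure propagates with the failing stage
    named; artifacts of completed stages remain on disk.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"outdir": str(out)}

    stages = [
        ("graph", [out / "nodes.tsv", out / "edges.tsv"]),
        ("walks", [out / "corpus.txt.gz"]),
        ("embed", [out / "embeddings.csv"]),
        ("cluster", [out / "labels.csv", out / "k_curve.csv", out / "metrics.json"]),
        ("enrich", [out / "enrichment.csv", out / "tfidf.csv"]),
        ("semsim", [out / "semsim.json"]),
    ]

    for stage, paths in stages:
        fresh = not all(p.exists() for p in paths)
        logger.info("stage %s: %s", stage, "running" if fresh else "cached")
        try:
            if stage == "graph" and fresh:
                _build_graph_stage(config, out)
            elif stage == "walks" and fresh:
                kg = read_kg(out / "nodes.tsv", out / "edges.tsv")
                wp = dataclasses.replace(
                    config.walk, seed=_stage_seed(config, "walks")
                )
                corpus = generate_walks(kg, wp)
                write_corpus(corpus, out / "corpus.txt.gz")
            elif stage == "embed" and fresh:
                corpus = read_corpus(out / "corpus.txt.gz")
                ep = dataclasses.replace(
                    config.embed, seed=_stage_seed(config, "embed")
                )
                emb = train_embedding(corpus, ep)
                emb.to_csv(out / "embeddings.csv")
                (out / "embed_params.json").write_text(
                    json.dumps(dataclasses.asdict(ep), indent=2)
                )
            elif stage == "cluster" and fresh:
                emb = EmbeddingMatrix.from_csv(out / "embeddings.csv")
                selected, curve, models = select_k(
                    emb,
                    k_min=config.k_min,
                    k_max=config.k_max,
                    seed=_stage_seed(config, "cluster"),
                    n_init=config.n_init,
                )
                if selected is None:  # no knee: fall back to best silhouette
                    scored = {
                        K: m.metrics.get("silhouette", float("-inf"))
                        for K, m in models.items()
                        if m.metrics
                    }
                    selected = max(scored, key=scored.get)
                model = models[selected]
                model.labels_frame().to_csv(out / "labels.csv", index=False)
                curve.to_csv(out / "k_curve.csv", index=False)
                (out / "metrics.json").write_text(
                    json.dumps(
                        {"selected_k": selected, "inertia": model.inertia,
                         **model.metrics},
                        indent=2,
                    )
                )
            elif stage == "enrich" and fresh:
                kg = read_kg(out / "nodes.tsv", out / "edges.tsv")
                labels_df = pd.read_csv(out / "labels.csv", dtype={"disease_id": str})
                labels = dict(zip(labels_df["disease_id"], labels_df["cluster"]))
                annotations = AnnotationSet.from_kg(kg)
                table = permutation_enrichment(
                    annotations,
                    labels,
                    B=config.permutations,
                    seed=_stage_seed(config, "enrich"),
                )
                table.to_csv(out / "enrichment.csv", index=False)
                corpus = read_corpus(out / "corpus.txt.gz")
                tfidf = tfidf_features(
                    corpus, labels, window=config.embed.window,
                    node_types=kg.nodes,
                )
                tfidf.to_csv(out / "tfidf.csv", index=False)
                summarize_by_percentile(
                    tfidf, config.percentile_thresholds
                ).to_csv(out / "tfidf_summary.csv", index=False)
                activity_path = out / "activity.tsv"
                if activity_path.exists():
                    activity = pd.read_csv(activity_path, sep="\t")
                    tdl_table, drug_table = summarize_drug_connections(
                        activity, annotations, labels
                    )
                    tdl_table.to_csv(out / "targets_by_tdl.csv", index=False)
                    drug_table.to_csv(out / "drugs_per_cluster.csv", index=False)
            elif stage == "semsim" and fresh:
                ont = load_obo(out / "validation.obo")
                labels_df = pd.read_csv(out / "labels.csv", dtype={"disease_id": str})
                labels = dict(zip(labels_df["disease_id"], labels_df["cluster"]))
                means = cluster_semsim(ont, labels)
                sizes = labels_df.groupby("cluster").size()
                set_size = config.set_size or max(2, round(float(sizes.mean())))
                pool = [d for d in labels if d in ont]
                null = null_semsim(
                    ont,
                    pool,
                    n_sets=config.n_sets,
                    set_size=min(set_size, len(pool)),
                    seed=_stage_seed(config, "semsim"),
                )
                t, p, report = semsim_t_test(
                    means, null, n_sets=config.n_sets, set_size=set_size
                )
                (out / "semsim.json").write_text(
                    json.dumps(report.to_dict(), indent=2)
                )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # gather results + manifest
    labels_df = pd.read_csv(out / "labels.csv", dtype={"disease_id": str})
    results["labels"] = dict(zip(labels_df["disease_id"], labels_df["cluster"]))
    results["metrics"] = json.loads((out / "metrics.json").read_text())
    results["selected_k"] = results["metrics"]["selected_k"]
    results["enrichment"] = pd.read_csv(out / "enrichment.csv")
    results["semsim"] = json.loads((out / "semsim.json").read_text())
    results["n_enriched_genes"] = int(
        results["enrichment"].loc[
            results["enrichment"]["q_value"] < config.fdr, "gene"
        ].nunique()
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: _stage_seed(config, s) for s, _ in stages},
        "walk": dataclasses.asdict(config.walk),
        "embed": dataclasses.asdict(config.embed),
        "k_range": [config.k_min, config.k_max],
        "permutations": config.permutations,
        "fdr": config.fdr,
        "checksums": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for _, paths in stages
            for p in paths
            if p.exists()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results


def end_to_end_recovery(config: PipelineConfig, outdir) -> dict:
    """Run the synthetic pipeline and score recovery of the planted clusters.

    Returns {"ari": adjusted Rand index of recovered vs planted labels,
    "selected_k": the kneedle-selected number of clusters}.
    """
    if config.synthetic is None:
        raise ValueError("end_to_end_recovery requires synthetic mode")
    results = run_all(config, outdir)
    truth = read_ground_truth(Path(outdir) / "ground_truth.csv")
    diseases = sorted(truth)
    ari = adjusted_rand_score(
        [truth[d] for d in diseases], [results["labels"][d] for d in diseases]
    )
    return {"ari": float(ari), "selected_k": int(results["selected_k"]), **results}
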