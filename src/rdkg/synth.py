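"""Synthetic knowledge graphs with planted disease-cluster structure.

The generator emulates, at desk scale, the shape of the real inputs: a set
of rare diseases partitioned into etiological modules, each module with its
own gene set and phenotype set; GO/HPO-like term hierarchies over genes and
phenotypes; within-module gene-gene pathway edges; small molecules attached
to genes with heavy-tailed degrees (echoing the observed power-law degree
distribution of the real network); and an ORDO-like validation ontology
whose subtrees mirror the planted clusters.  Ground-truth labels make every
downstream stage testable without downloads.

Noise is modeled as *rewiring*: each disease annotation is, with probability
``annotation_noise``, redirected to a uniformly random out-of-module target
of the same kind, so annotation counts are held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import KnowledgeGraph
from .ontology import OntologyDAG

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_ontology",
    "generate_kg",
    "generate_validation_ontology",
    "generate_activity_table",
    "write_ground_truth",
    "read_ground_truth",
]

#: Pharos-wide TDL frequencies (Tclin, Tchem, Tbio, Tdark) used as sampling
#: weights for synthetic target-development-level labels.
_TDL_LEVELS = ("Tclin", "Tchem", "Tbio", "Tdark")
_TDL_WEIGHTS = np.array([685, 1930, 11867, 5932], dtype=float)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic knowledge graph."""

    n_clusters: int = 8
    diseases_per_cluster: int = 30
    genes_per_module: int = 8
    phenotypes_per_module: int = 12
    annotation_noise: float = 0.0
    ontology_depth: int = 3
    ontology_branching: int = 3
    n_small_molecules: int = 50
    pathway_edge_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_clusters",
            "diseases_per_cluster",
            "genes_per_module",
            "phenotypes_per_module",
            "ontology_depth",
            "ontology_branching",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_small_molecules < 0:
            raise ValueError("n_small_molecules must be nonnegative")
        for name in ("annotation_noise", "pathway_edge_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure: the labels the pipeline should recover."""

    disease_labels: dict[str, int] = field(default_factory=dict)
    module_genes: dict[int, set[str]] = field(default_factory=dict)
    module_phenotypes: dict[int, set[str]] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.module_genes)


def generate_ontology(
    depth: int, branching: int, seed: int = 0, prefix: str = "T"
) -> OntologyDAG:
    """A complete rooted tree: sum_{i=0..depth} branching**i terms.

    The topology is deterministic given (depth, branching); ``seed`` is part
    of the signature for interface symmetry with the other generators.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be positive integers")
    ont = OntologyDAG()
    counter = 1
    root = f"{prefix}:{counter:07d}"
    ont.add_term(root, f"{prefix} root")
    frontier = [root]
    for level in range(depth):
        nxt: list[str] = []
        for parent in frontier:
            for _ in range(branching):
                counter += 1
                term = f"{prefix}:{counter:07d}"
                ont.add_term(term, f"{prefix} level-{level + 1} term {counter}")
                ont.add_is_a(term, parent)
                nxt.append(term)
        frontier = nxt
    return ont


def _maybe_rewire(
    target: str, pool_other: list[str], noise: float, rng: np.random.Generator
) -> str:
    if noise > 0 and pool_other and rng.random() < noise:
        return pool_other[rng.integers(len(pool_other))]
    return target


def generate_kg(config: SyntheticConfig) -> tuple[KnowledgeGraph, GroundTruth]:
    """Build the synthetic heterogeneous graph and its ground truth.

    Structure at noise 0: disease-gene and disease-phenotype adjacency is
    exactly block-diagonal under the planted labels (each disease annotated
    to every gene and phenotype of its module); genes and phenotypes each
    attach to up to two random ontology leaves; gene-gene pathway edges are
    Bernoulli(``pathway_edge_prob``) within modules; small molecules attach
    to Zipf-distributed numbers of random genes with an "activity" edge.
    """
    rng = np.random.default_rng(config.seed)
    go = generate_ontology(
        config.ontology_depth, config.ontology_branching, config.seed, prefix="GO"
    )
    hpo = generate_ontology(
        config.ontology_depth, config.ontology_branching, config.seed, prefix="HP"
    )

    kg = KnowledgeGraph()
    for term in sorted(go.terms):
        kg.add_node(term, "go_term")
    for term in sorted(hpo.terms):
        kg.add_node(term, "hpo_term")
    for child, parent in sorted(go.is_a | hpo.is_a):
        kg.add_edge(child, "is_a", parent)

    truth = GroundTruth()
    diseases: dict[int, list[str]] = {}
    genes: dict[int, list[str]] = {}
    phenos: dict[int, list[str]] = {}
    for c in range(config.n_clusters):
        diseases[c] = [
            f"D{c:02d}_{i:03d}" for i in range(config.diseases_per_cluster)
        ]
        genes[c] = [f"G{c:02d}_{j:03d}" for j in range(config.genes_per_module)]
        phenos[c] = [f"P{c:02d}_{j:03d}" for j in range(config.phenotypes_per_module)]
        for d in diseases[c]:
            kg.add_node(d, "disease")
            truth.disease_labels[d] = c
        for g in genes[c]:
            kg.add_node(g, "gene")
        for p in phenos[c]:
            kg.add_node(p, "phenotype")
        truth.module_genes[c] = set(genes[c])
        truth.module_phenotypes[c] = set(phenos[c])

    all_genes = [g for c in range(config.n_clusters) for g in genes[c]]
    all_phenos = [p for c in range(config.n_clusters) for p in phenos[c]]

    # disease annotations, independently rewired with probability noise
    for c in range(config.n_clusters):
        out_genes = [g for g in all_genes if g not in truth.module_genes[c]]
        out_phenos = [p for p in all_phenos if p not in truth.module_phenotypes[c]]
        for d in diseases[c]:
            for g in genes[c]:
                kg.add_edge(
                    d,
                    "has_gene",
                    _maybe_rewire(g, out_genes, config.annotation_noise, rng),
                )
            for p in phenos[c]:
                kg.add_edge(
                    d,
                    "has_phenotype",
                    _maybe_rewire(p, out_phenos, config.annotation_noise, rng),
                )

    # ontology attachment: up to two random leaves per gene / phenotype
    go_leaves = sorted(go.leaves)
    hpo_leaves = sorted(hpo.leaves)
    for g in all_genes:
        k = min(2, len(go_leaves))
        for term in rng.choice(go_leaves, size=k, replace=False):
            kg.add_edge(g, "annotated_to", str(term))
    for p in all_phenos:
        k = min(2, len(hpo_leaves))
        for term in rng.choice(hpo_leaves, size=k, replace=False):
            kg.add_edge(p, "annotated_to", str(term))

    # within-module pathway edges
    for c in range(config.n_clusters):
        mod = genes[c]
        for i in range(len(mod)):
            for j in range(i + 1, len(mod)):
                if rng.random() < config.pathway_edge_prob:
                    kg.add_edge(mod[i], "interacts_with", mod[j])

    # small molecules with heavy-tailed target degrees
    for m in range(config.n_small_molecules):
        sm = f"CID{m:05d}"
        kg.add_node(sm, "small_molecule")
        deg = int(min(rng.zipf(2.0), len(all_genes)))
        targets = rng.choice(all_genes, size=deg, replace=False)
        for g in targets:
            kg.add_edge(sm, "activity", str(g))

    return kg, truth


def generate_validation_ontology(truth: GroundTruth, seed: int = 0) -> OntologyDAG:
    """ORDO-like hierarchy aligned with the planted clusters.

    One subtree per planted cluster under a shared root, with disease ids as
    leaves, so within-cluster disease pairs share a deeper (more informative)
    common ancestor than between-cluster pairs.  Clusters with at least four
    diseases are further split into two nested subgroup terms of seeded
    random sizes, echoing ORDO's irregular class structure; the irregularity
    makes within-cluster mean similarity differ across clusters, as it does
    for real disease groups.
    """
    if not truth.disease_labels:
        raise ValueError("empty ground truth")
    rng = np.random.default_rng(seed)
    ont = OntologyDAG()
    root = "RD:0000000"
    ont.add_term(root, "rare disease root")
    by_cluster: dict[int, list[str]] = {}
    for d, c in sorted(truth.disease_labels.items()):
        by_cluster.setdefault(c, []).append(d)
    for c in sorted(by_cluster):
        term = f"RD:{c + 1:07d}"
        ont.add_term(term, f"disease group {c}")
        ont.add_is_a(term, root)
        members = by_cluster[c]
        if len(members) >= 4:
            n1 = int(rng.integers(2, len(members) - 1))
            sub_a = f"RD:{c + 1:07d}a"
            sub_b = f"RD:{c + 1:07d}b"
            ont.add_term(sub_a, f"disease subgroup {c}a")
            ont.add_term(sub_b, f"disease subgroup {c}b")
            ont.add_is_a(sub_a, term)
            ont.add_is_a(sub_b, term)
            shuffled = list(members)
            rng.shuffle(shuffled)
            for d in shuffled[:n1]:
                ont.add_term(d, d)
                ont.add_is_a(d, sub_a)
            for d in shuffled[n1:]:
                ont.add_term(d, d)
                ont.add_is_a(d, sub_b)
        else:
            for d in members:
                ont.add_term(d, d)
                ont.add_is_a(d, term)
    return ont


def generate_activity_table(kg: KnowledgeGraph, seed: int = 0) -> pd.DataFrame:
    """Pharos-style target-ligand table derived from the graph's activity edges.

    Each target receives one TDL label sampled with the Pharos-wide
    frequencies; each ligand is an approved drug with probability 0.25.
    Columns: target, ligand, is_approved_drug, tdl.
    """
    rng = np.random.default_rng(seed)
    pairs = sorted(
        (t, s) for s, rel, t in kg.edges if rel == "activity"
    )  # (gene target, small molecule)
    targets = sorted({t for t, _ in pairs})
    ligands = sorted({l for _, l in pairs})
    tdl_of = {
        t: rng.choice(_TDL_LEVELS, p=_TDL_WEIGHTS / _TDL_WEIGHTS.sum())
        for t in targets
    }
    approved = {l: bool(rng.random() < 0.25) for l in ligands}
    return pd.DataFrame(
        [
            {
                "target": t,
                "ligand": l,
                "is_approved_drug": approved[l],
                "tdl": tdl_of[t],
            }
            for t, l in pairs
        ]
    )


def generate_null_annotations(
    seed: int,
    n_diseases: int = 12000,
    cluster_probs: tuple[float, ...] = (0.12, 0.16, 0.20, 0.24, 0.28),
    n_genes: int = 700,
    annotations_range: tuple[int, int] = (5000, 7000),
):
    """Exchangeable-null benchmark: annotations independent of labels.

    Diseases are assigned to clusters of unequal expected sizes (real
    cluster-size distributions are skewed) independently of their gene
    annotations; each gene annotates a uniformly random disease subset whose
    size is drawn from ``annotations_range``.  The sizes are deliberately
    large so the permutation count statistic has standard deviation well
    above 10: p-value calibration diagnostics (uniformity of the ECDF)
    presume a near-continuous null, which small counts violate by
    discreteness.  Returns ``(AnnotationSet, labels)`` for feeding
    :func:`rdkg.enrich.permutation_enrichment`.
    """
    from .graph import AnnotationSet

    rng = np.random.default_rng(seed)
    probs = np.asarray(cluster_probs, dtype=float)
    probs = probs / probs.sum()
    diseases = [f"d{i:05d}" for i in range(n_diseases)]
    lab = rng.choice(len(probs), size=n_diseases, p=probs)
    labels = {d: int(c) for d, c in zip(diseases, lab)}
    ann = AnnotationSet()
    lo, hi = annotations_range
    for g in range(n_genes):
        m = int(rng.integers(lo, hi + 1))
        for i in rng.choice(n_diseases, m, replace=False):
            ann.disease_to_genes.setdefault(diseases[i], set()).add(f"g{g:04d}")
    return ann, labels


def write_ground_truth(truth: GroundTruth, path) -> None:
    pd.DataFrame(
        sorted(truth.disease_labels.items()), columns=["disease_id", "cluster"]
    ).to_csv(path, index=False)


def read_ground_truth(path) -> dict[str, int]:
    df = pd.read_csv(path, dtype={"disease_id": str, "cluster": int})
    return dict(zip(df["disease_id"], df["cluster"]))
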