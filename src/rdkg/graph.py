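"""Heterogeneous knowledge-graph assembly and exploratory statistics.

The knowledge graph holds typed biomedical entities — diseases, genes,
phenotypes, GO/HPO terms, small molecules, pathways — connected by labeled
relations.  Edges are stored directed as read but traversed undirected
everywhere, so random walks move freely up and down the ontology layers.
Diseases connect only to genes and phenotypes; everything else reaches a
disease through those two bridges.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ontology import OntologyDAG

__all__ = [
    "NODE_TYPES",
    "KnowledgeGraph",
    "AnnotationSet",
    "harmonize_ids",
    "assemble_graph",
    "degree_distribution",
    "disease_shortest_paths",
    "write_kg",
    "read_kg",
]

NODE_TYPES = frozenset(
    {"disease", "gene", "phenotype", "go_term", "hpo_term", "small_molecule", "pathway"}
)


class KnowledgeGraph:
    """Typed node store plus a set of (source, relation, target) triples.

    Duplicate triples collapse; multi-edges with distinct relation labels
    between the same node pair are all kept, since each relation label is a
    distinct walk token.
    """

    def __init__(self) -> None:
        self._types: dict[str, str] = {}
        self._edges: set[tuple[str, str, str]] = set()
        self._adj: dict[str, tuple[tuple[str, str], ...]] | None = None

    # -- construction -------------------------------------------------
    def add_node(self, node: str, ntype: str) -> None:
        if ntype not in NODE_TYPES:
            raise ValueError(f"unknown node type {ntype!r} for node {node!r}")
        prev = self._types.get(node)
        if prev is not None and prev != ntype:
            raise ValueError(f"node {node!r} already typed {prev!r}, got {ntype!r}")
        self._types[node] = ntype
        self._adj = None

    def add_edge(self, source: str, relation: str, target: str) -> None:
        for endpoint in (source, target):
            if endpoint not in self._types:
                raise KeyError(f"edge endpoint {endpoint!r} is not a known node")
        self._edges.add((source, relation, target))
        self._adj = None

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> Mapping[str, str]:
        return self._types

    @property
    def edges(self) -> frozenset[tuple[str, str, str]]:
        return frozenset(self._edges)

    @property
    def n_nodes(self) -> int:
        return len(self._types)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, node: str) -> bool:
        return node in self._types

    def node_type(self, node: str) -> str:
        try:
            return self._types[node]
        except KeyError:
            raise KeyError(f"unknown node: {node!r}") from None

    def nodes_of_type(self, ntype: str) -> list[str]:
        return sorted(n for n, t in self._types.items() if t == ntype)

    def adjacency(self) -> dict[str, tuple[tuple[str, str], ...]]:
        """Undirected adjacency: node -> sorted tuple of (relation, neighbor)."""
        if self._adj is None:
            adj: dict[str, list[tuple[str, str]]] = {n: [] for n in self._types}
            for s, rel, t in self._edges:
                adj[s].append((rel, t))
                adj[t].append((rel, s))
            self._adj = {n: tuple(sorted(entries)) for n, entries in adj.items()}
        return self._adj

    def neighbors(self, node: str) -> tuple[tuple[str, str], ...]:
        if node not in self._types:
            raise KeyError(f"unknown node: {node!r}")
        return self.adjacency()[node]

    def degree(self, node: str) -> int:
        return len(self.neighbors(node))


@dataclass
class AnnotationSet:
    """Direct disease annotations: the only edges touching disease nodes."""

    disease_to_genes: dict[str, set[str]] = field(default_factory=dict)
    disease_to_phenotypes: dict[str, set[str]] = field(default_factory=dict)

    @property
    def diseases(self) -> set[str]:
        return set(self.disease_to_genes) | set(self.disease_to_phenotypes)

    @classmethod
    def from_kg(cls, kg: KnowledgeGraph) -> "AnnotationSet":
        """Recover annotations from a graph's disease edges."""
        out = cls()
        for d in kg.nodes_of_type("disease"):
            genes = {n for _, n in kg.neighbors(d) if kg.node_type(n) == "gene"}
            phenos = {n for _, n in kg.neighbors(d) if kg.node_type(n) == "phenotype"}
            if genes:
                out.disease_to_genes[d] = genes
            if phenos:
                out.disease_to_phenotypes[d] = phenos
        return out


# ----------------------------------------------------------------------
# identifier harmonization
# ----------------------------------------------------------------------

def _canonical_ids(
    ident: str,
    forward: Mapping[str, frozenset[str]],
    memo: dict[str, tuple[str, ...]],
    stack: set[str],
) -> tuple[str, ...]:
    if ident in memo:
        return memo[ident]
    if ident not in forward:
        memo[ident] = (ident,)
        return memo[ident]
    if ident in stack:
        raise ValueError(f"circular identifier mapping involving {ident!r}")
    stack.add(ident)
    out: list[str] = []
    for nxt in sorted(forward[ident]):
        out.extend(_canonical_ids(nxt, forward, memo, stack))
    stack.discard(ident)
    memo[ident] = tuple(dict.fromkeys(out))
    return memo[ident]


def harmonize_ids(
    edges: pd.DataFrame, mappings: Sequence[pd.DataFrame]
) -> tuple[pd.DataFrame, dict]:
    """Rewrite edge endpoints to a canonical namespace.

    ``mappings`` are two-column tables (source id, target id), e.g.
    ChEMBL->ChEBI and ChEBI->PubChem; mappings are applied transitively until
    an id has no further mapping.  Unmapped ids are kept verbatim and counted.
    One-to-many mappings are kept (the edge is duplicated per canonical id)
    and reported.  Circular mapping chains raise ``ValueError``.
    """
    forward: dict[str, set[str]] = {}
    for table in mappings:
        src_col, dst_col = table.columns[:2]
        for src, dst in zip(table[src_col], table[dst_col]):
            forward.setdefault(str(src), set()).add(str(dst))
    frozen = {k: frozenset(v) for k, v in forward.items()}
    memo: dict[str, tuple[str, ...]] = {}

    mapped: set[str] = set()
    unmapped: set[str] = set()
    ambiguous: dict[str, tuple[str, ...]] = {}

    rows: list[tuple[str, str, str]] = []
    for source, relation, target in zip(
        edges["source"], edges["relation"], edges["target"]
    ):
        resolved = []
        for endpoint in (str(source), str(target)):
            canon = _canonical_ids(endpoint, frozen, memo, set())
            if canon == (endpoint,) and endpoint not in frozen:
                unmapped.add(endpoint)
            else:
                mapped.add(endpoint)
            if len(canon) > 1:
                ambiguous[endpoint] = canon
            resolved.append(canon)
        for s in resolved[0]:
            for t in resolved[1]:
                rows.append((s, relation, t))
    out = pd.DataFrame(rows, columns=["source", "relation", "target"])
    out = out.drop_duplicates(ignore_index=True)
    report = {
        "n_mapped_ids": len(mapped),
        "n_unmapped_ids": len(unmapped),
        "unmapped_ids": sorted(unmapped),
        "ambiguous": {k: list(v) for k, v in sorted(ambiguous.items())},
    }
    return out, report


# ----------------------------------------------------------------------
# graph assembly
# ----------------------------------------------------------------------

def assemble_graph(
    annotations: AnnotationSet,
    gene_ont: OntologyDAG,
    pheno_ont: OntologyDAG,
    gene_go_annotations: Mapping[str, Iterable[str]] | None = None,
    interaction_edges: pd.DataFrame | None = None,
    activity_edges: pd.DataFrame | None = None,
    pheno_term_annotations: Mapping[str, Iterable[str]] | None = None,
) -> KnowledgeGraph:
    """Union the inputs into one typed graph.

    Expects annotation pruning and id harmonization to have been applied
    already.  Diseases connect only to genes ("has_gene") and phenotypes
    ("has_phenotype"); ontology edges carry relation "is_a"; gene->GO and
    phenotype->HPO attachments carry "annotated_to"; interaction edges keep
    their own relation labels; small-molecule activity edges carry
    "activity".  Duplicate triples collapse.
    """
    kg = KnowledgeGraph()
    for term in gene_ont.terms:
        kg.add_node(term, "go_term")
    for term in pheno_ont.terms:
        kg.add_node(term, "hpo_term")
    for d in annotations.diseases:
        kg.add_node(d, "disease")
    for genes in annotations.disease_to_genes.values():
        for g in genes:
            kg.add_node(g, "gene")
    for phenos in annotations.disease_to_phenotypes.values():
        for p in phenos:
            if p not in kg:
                kg.add_node(p, "phenotype")
    if gene_go_annotations:
        for g in gene_go_annotations:
            if g not in kg:
                kg.add_node(g, "gene")
    if interaction_edges is not None:
        for col in ("source", "target"):
            for n in interaction_edges[col]:
                if str(n) not in kg:
                    kg.add_node(str(n), "gene")
    if activity_edges is not None:
        for lig in activity_edges["ligand"]:
            if str(lig) not in kg:
                kg.add_node(str(lig), "small_molecule")

    for d, genes in annotations.disease_to_genes.items():
        for g in genes:
            kg.add_edge(d, "has_gene", g)
    for d, phenos in annotations.disease_to_phenotypes.items():
        for p in phenos:
            kg.add_edge(d, "has_phenotype", p)
    for child, parent in gene_ont.is_a | pheno_ont.is_a:
        kg.add_edge(child, "is_a", parent)

    offenders: list[tuple[str, str, str]] = []

    def _safe_edge(s: str, rel: str, t: str) -> None:
        if s not in kg or t not in kg:
            offenders.append((s, rel, t))
        else:
            kg.add_edge(s, rel, t)

    if gene_go_annotations:
        for g, terms in gene_go_annotations.items():
            for t in terms:
                _safe_edge(g, "annotated_to", t)
    if pheno_term_annotations:
        for p, terms in pheno_term_annotations.items():
            for t in terms:
                _safe_edge(p, "annotated_to", t)
    if interaction_edges is not None:
        for s, rel, t in zip(
            interaction_edges["source"],
            interaction_edges["relation"],
            interaction_edges["target"],
        ):
            _safe_edge(str(s), str(rel), str(t))
    if activity_edges is not None:
        for lig, tgt in zip(activity_edges["ligand"], activity_edges["target"]):
            _safe_edge(str(lig), "activity", str(tgt))
    if offenders:
        raise ValueError(
            "edges reference nodes that could not be typed: "
            + ", ".join(map(str, offenders[:10]))
            + ("..." if len(offenders) > 10 else "")
        )
    return kg


# ----------------------------------------------------------------------
# exploratory statistics
# ----------------------------------------------------------------------

def degree_distribution(kg: KnowledgeGraph) -> dict:
    """Histogram of undirected node degree, overall and per node type."""
    if kg.n_nodes == 0:
        raise ValueError("degree distribution of an empty graph")
    adj = kg.adjacency()
    overall: Counter[int] = Counter()
    per_type: dict[str, Counter[int]] = {}
    for node, entries in adj.items():
        deg = len(entries)
        overall[deg] += 1
        per_type.setdefault(kg.node_type(node), Counter())[deg] += 1
    return {
        "overall": dict(overall),
        "per_type": {t: dict(c) for t, c in per_type.items()},
    }


def disease_shortest_paths(kg: KnowledgeGraph) -> dict:
    """Shortest-path-length distribution over all unordered disease pairs.

    Paths run on the undirected graph through any node type; unreachable
    pairs are reported separately, never mixed into the distribution.
    """
    diseases = kg.nodes_of_type("disease")
    if len(diseases) < 2:
        raise ValueError("need at least two disease nodes")
    adj = kg.adjacency()
    plain = {n: sorted({nbr for _, nbr in entries}) for n, entries in adj.items()}
    order = {d: i for i, d in enumerate(diseases)}
    lengths: Counter[int] = Counter()
    unreachable = 0
    for d in diseases:
        dist = {d: 0}
        queue = deque([d])
        while queue:
            cur = queue.popleft()
            for nbr in plain[cur]:
                if nbr not in dist:
                    dist[nbr] = dist[cur] + 1
                    queue.append(nbr)
        for other in diseases:
            if order[other] <= order[d]:
                continue
            if other in dist:
                lengths[dist[other]] += 1
            else:
                unreachable += 1
    return {"lengths": dict(lengths), "unreachable_pairs": unreachable}


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def write_kg(kg: KnowledgeGraph, nodes_path, edges_path) -> None:
    """Serialize as two sorted TSVs: (id, type) and (source, relation, target)."""
    nodes = pd.DataFrame(sorted(kg.nodes.items()), columns=["id", "type"])
    nodes.to_csv(nodes_path, sep="\t", index=False)
    edges = pd.DataFrame(sorted(kg.edges), columns=["source", "relation", "target"])
    edges.to_csv(edges_path, sep="\t", index=False)


def read_kg(nodes_path, edges_path) -> KnowledgeGraph:
    kg = KnowledgeGraph()
    nodes = pd.read_csv(nodes_path, sep="\t", dtype=str)
    for node, ntype in zip(nodes["id"], nodes["type"]):
        kg.add_node(node, ntype)
    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    for s, rel, t in zip(edges["source"], edges["relation"], edges["target"]):
        kg.add_edge(s, rel, t)
    return kg
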