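"""Type-balanced random walks over the knowledge graph.

Walks emanate from every disease node.  Most diseases carry far more
phenotype annotations than gene annotations, so a uniform neighbor choice
would drown the gene signal; at any visit to a disease node that has both
gene and phenotype neighbors, the walker therefore first picks the gene
branch or the phenotype branch with probability 1/2 and only then a uniform
neighbor within that branch.  All other nodes step uniformly over all
neighbors.  Edge relation labels are emitted as tokens between node tokens
(DL2Vec convention), so relations contribute context to the embedding.

A walk of length ``L`` takes L node-steps after the start node and yields at
most ``2L + 1`` tokens (nodes interleaved with edge labels); dead ends
truncate the walk.  Each disease draws from its own random stream derived
from (seed, disease-id), so corpora are reproducible regardless of
generation order.
"""

from __future__ import annotations

import gzip
import hashlib
import random
from dataclasses import dataclass

from .graph import KnowledgeGraph

__all__ = [
    "WalkParams",
    "WalkCorpus",
    "walk_step",
    "generate_walks",
    "write_corpus",
    "read_corpus",
]


@dataclass(frozen=True)
class WalkParams:
    walks_per_disease: int = 250
    walk_length: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walks_per_disease < 1 or self.walk_length < 1:
            raise ValueError("walks_per_disease and walk_length must be >= 1")


@dataclass
class WalkCorpus:
    """Token sequences; each walk starts (and ends) on a node token."""

    walks: list[list[str]]
    params: WalkParams | None = None

    def __len__(self) -> int:
        return len(self.walks)

    def __iter__(self):
        return iter(self.walks)


def derive_seed(seed: int, name: str) -> int:
    """Stable per-name substream seed (independent of hash randomization)."""
    digest = hashlib.blake2b(f"{seed}:{name}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**63)


def _branches(kg: KnowledgeGraph, node: str):
    entries = kg.neighbors(node)
    genes = tuple(e for e in entries if kg.node_type(e[1]) == "gene")
    phenos = tuple(e for e in entries if kg.node_type(e[1]) == "phenotype")
    return entries, genes, phenos


def walk_step(
    kg: KnowledgeGraph, current: str, rng: random.Random
) -> tuple[str, str] | None:
    """One transition from ``current``; returns (edge label, next node).

    Disease nodes with both gene and phenotype neighbors flip a fair coin
    between the two branches; any other node (or a disease with a single
    neighbor type) steps uniformly.  A node with no neighbors ends the walk
    (returns None).
    """
    if current not in kg:
        raise KeyError(f"unknown node: {current!r}")
    entries = kg.neighbors(current)
    if not entries:
        return None
    pool = entries
    if kg.node_type(current) == "disease":
        _, genes, phenos = _branches(kg, current)
        if genes and phenos:
            pool = genes if rng.random() < 0.5 else phenos
    return pool[rng.randrange(len(pool))]


def generate_walks(kg: KnowledgeGraph, params: WalkParams) -> WalkCorpus:
    """W walks of L node-steps from every disease node."""
    diseases = kg.nodes_of_type("disease")
    if not diseases:
        raise ValueError("graph has no disease nodes")
    adj = kg.adjacency()
    types = kg.nodes
    # Precompute branch splits once; the walker consults them at every visit.
    branch: dict[str, tuple[tuple, tuple]] = {}
    for d in diseases:
        genes = tuple(e for e in adj[d] if types[e[1]] == "gene")
        phenos = tuple(e for e in adj[d] if types[e[1]] == "phenotype")
        branch[d] = (genes, phenos)
    is_disease = {n: (t == "disease") for n, t in types.items()}

    walks: list[list[str]] = []
    for disease in diseases:
        rng = random.Random(derive_seed(params.seed, disease))
        for _ in range(params.walks_per_disease):
            tokens = [disease]
            current = disease
            for _ in range(params.walk_length):
                entries = adj[current]
                if not entries:
                    break
                pool = entries
                if is_disease[current]:
                    genes, phenos = branch.get(current) or _branches(kg, current)[1:]
                    if genes and phenos:
                        pool = genes if rng.random() < 0.5 else phenos
                rel, nxt = pool[rng.randrange(len(pool))]
                tokens.append(rel)
                tokens.append(nxt)
                current = nxt
            walks.append(tokens)
    return WalkCorpus(walks, params)


def write_corpus(corpus: WalkCorpus, path) -> None:
    """One walk per line, space-separated tokens, gzip text."""
    with gzip.open(path, "wt") as out:
        for walk in corpus.walks:
            for token in walk:
                if any(ch.isspace() for ch in token):
                    raise ValueError(f"token contains whitespace: {token!r}")
            out.write(" ".join(walk) + "\n")


def read_corpus(path) -> WalkCorpus:
    with gzip.open(path, "rt") as handle:
        walks = [line.split() for line in handle if line.strip()]
    return WalkCorpus(walks, None)
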