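"""Ontology term hierarchies: container, OBO I/O, and annotation pruning.

An :class:`OntologyDAG` holds the asserted ``is_a`` hierarchy of an OBO
ontology (GO, HPO, ORDO or a synthetic stand-in).  Only subsumption edges are
kept: every downstream computation in this package (redundant-annotation
pruning, Sanchez information content, most-informative common ancestors)
needs ancestor/descendant relations and nothing else.  No OWL reasoning is
performed; the asserted hierarchy plus transitive ancestor queries is the
deliberate simplification documented in ``docs/methods.md``.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "OntologyDAG",
    "load_obo",
    "write_obo",
    "prune_subtree",
    "prune_redundant_annotations",
]


class OntologyDAG:
    """A rooted, acyclic ``is_a`` hierarchy of ontology terms.

    Edges are stored child -> parent.  A term may have several parents
    (a DAG, not necessarily a tree) and the ontology may have several roots.
    """

    def __init__(
        self,
        names: Mapping[str, str] | None = None,
        is_a: Iterable[tuple[str, str]] = (),
    ) -> None:
        self._g = nx.DiGraph()
        self._names: dict[str, str] = {}
        if names:
            for term, name in names.items():
                self.add_term(term, name)
        for child, parent in is_a:
            self.add_is_a(child, parent)

    # -- construction -------------------------------------------------
    def add_term(self, term: str, name: str | None = None) -> None:
        self._g.add_node(term)
        if name is not None:
            self._names[term] = name
        self._invalidate()

    def add_is_a(self, child: str, parent: str) -> None:
        """Assert ``child is_a parent``; both terms are created if absent."""
        self._g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self._g):
            self._g.remove_edge(child, parent)
            raise ValueError(f"is_a edge {child!r} -> {parent!r} creates a cycle")
        self._invalidate()

    def _invalidate(self) -> None:
        # Caches built lazily by the semantic-similarity layer.
        self.__dict__.pop("_semsim_cache", None)

    # -- basic queries -------------------------------------------------
    @property
    def terms(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def names(self) -> dict[str, str]:
        return dict(self._names)

    def name(self, term: str) -> str:
        return self._names.get(term, term)

    @property
    def is_a(self) -> set[tuple[str, str]]:
        return set(self._g.edges)

    @property
    def roots(self) -> set[str]:
        return {t for t in self._g.nodes if self._g.out_degree(t) == 0}

    @property
    def leaves(self) -> set[str]:
        return {t for t in self._g.nodes if self._g.in_degree(t) == 0}

    def __contains__(self, term: str) -> bool:
        return term in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyDAG):
            return NotImplemented
        return self.terms == other.terms and self.is_a == other.is_a

    def parents(self, term: str) -> set[str]:
        self._require(term)
        return set(self._g.successors(term))

    def children(self, term: str) -> set[str]:
        self._require(term)
        return set(self._g.predecessors(term))

    def ancestors(self, term: str, include_self: bool = False) -> set[str]:
        """All terms reachable from ``term`` by following is_a upward."""
        self._require(term)
        anc = nx.descendants(self._g, term)  # child->parent orientation
        if include_self:
            anc = anc | {term}
        return anc

    def descendants(self, term: str, include_self: bool = False) -> set[str]:
        self._require(term)
        des = nx.ancestors(self._g, term)
        if include_self:
            des = des | {term}
        return des

    def _require(self, term: str) -> None:
        if term not in self._g:
            raise KeyError(f"unknown ontology term: {term!r}")

    def copy(self) -> "OntologyDAG":
        out = OntologyDAG()
        out._g = self._g.copy()
        out._names = dict(self._names)
        return out


def load_obo(path) -> OntologyDAG:
    """Load an OBO 1.2/1.4 file into an :class:`OntologyDAG`.

    One term per non-obsolete ``[Term]`` stanza; only asserted ``is_a``
    edges are kept (``part_of`` and other relationship types are ignored).
    Obsolete terms are dropped.
    """
    with open(path) as handle:  # raises FileNotFoundError for missing files
        try:
            graph = obonet.read_obo(handle)  # ignores obsolete stanzas
        except Exception as exc:  # pragma: no cover - passthrough detail
            raise ValueError(f"failed to parse OBO file {path}: {exc}") from exc
    ont = OntologyDAG()
    for term, data in graph.nodes(data=True):
        ont.add_term(term, data.get("name"))
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            ont.add_is_a(child, parent)
    return ont


def write_obo(ont: OntologyDAG, path) -> None:
    """Write the hierarchy as a minimal OBO 1.2 document (id/name/is_a)."""
    with open(path, "w") as out:
        out.write("format-version: 1.2\n")
        out.write("ontology: rdkg\n")
        for term in sorted(ont.terms):
            out.write("\n[Term]\n")
            out.write(f"id: {term}\n")
            out.write(f"name: {ont.name(term)}\n")
            for parent in sorted(ont.parents(term)):
                out.write(f"is_a: {parent} ! {ont.name(parent)}\n")


def prune_subtree(ont: OntologyDAG, term: str) -> OntologyDAG:
    """Return a copy of ``ont`` with ``term`` and all its is_a descendants
    removed, together with their incident edges.

    Used to drop hierarchy branches that over-connect the graph without
    carrying disease-relevant meaning (e.g. HPO's mode-of-inheritance
    subtree, HP:0000005).
    """
    if term not in ont:
        raise KeyError(f"unknown ontology term: {term!r}")
    doomed = ont.descendants(term, include_self=True)
    out = ont.copy()
    out._g.remove_nodes_from(doomed)
    for t in doomed:
        out._names.pop(t, None)
    out._invalidate()
    return out


def prune_redundant_annotations(
    annotations: Mapping[str, set[str]], ont: OntologyDAG
) -> dict[str, set[str]]:
    """Keep only the most specific term of each annotated ancestor chain.

    When an entity is annotated to two terms in a subsumption relation
    (e.g. a gene annotated to both protein binding and kinase binding),
    only the lowest subclass carries non-redundant information; every term
    that is a proper is_a ancestor of another annotated term of the same
    entity is removed.  Idempotent.
    """
    pruned: dict[str, set[str]] = {}
    for entity, terms in annotations.items():
        for t in terms:
            if t not in ont:
                raise ValueError(
                    f"entity {entity!r} annotated to unknown term {t!r}"
                )
        redundant: set[str] = set()
        for t in terms:
            redundant |= ont.ancestors(t) & set(terms)  # proper ancestors only
        pruned[entity] = set(terms) - redundant
    return pruned
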