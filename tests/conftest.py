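import pytest

from rdkg import (
    KnowledgeGraph,
    OntologyDAG,
    SyntheticConfig,
    generate_kg,
)


@pytest.fixture()
def toy_ontology() -> OntologyDAG:
    """R -> {A, B}; A -> {L1, L2}; B -> {L3} (7-term Sanchez fixture)."""
    ont = OntologyDAG()
    for term in ("R", "A", "B", "L1", "L2", "L3"):
        ont.add_term(term)
    ont.add_is_a("A", "R")
    ont.add_is_a("B", "R")
    ont.add_is_a("L1", "A")
    ont.add_is_a("L2", "A")
    ont.add_is_a("L3", "B")
    return ont


@pytest.fixture()
def seven_term_tree() -> OntologyDAG:
    """Full binary tree of depth 2: root, 2 mid-level terms, 4 leaves."""
    ont = OntologyDAG()
    edges = [("m1", "root"), ("m2", "root"),
             ("l1", "m1"), ("l2", "m1"), ("l3", "m2"), ("l4", "m2")]
    for child, parent in edges:
        ont.add_is_a(child, parent)
    return ont


@pytest.fixture()
def tiny_kg() -> KnowledgeGraph:
    """One disease with one gene and three phenotypes (walk-balance fixture)."""
    kg = KnowledgeGraph()
    kg.add_node("d1", "disease")
    kg.add_node("g1", "gene")
    for p in ("p1", "p2", "p3"):
        kg.add_node(p, "phenotype")
        kg.add_edge("d1", "has_phenotype", p)
    kg.add_edge("d1", "has_gene", "g1")
    return kg


@pytest.fixture(scope="session")
def small_synth():
    """3 planted clusters x 10 diseases, noise 0 (shared read-only)."""
    config = SyntheticConfig(
        n_clusters=3,
        diseases_per_cluster=10,
        genes_per_module=4,
        phenotypes_per_module=6,
        ontology_depth=2,
        ontology_branching=2,
        n_small_molecules=10,
        seed=101,
    )
    kg, truth = generate_kg(config)
    return config, kg, truth
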