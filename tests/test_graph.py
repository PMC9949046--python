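import networkx as nx
import pandas as pd
import pytest

from rdkg import (
    AnnotationSet,
    KnowledgeGraph,
    OntologyDAG,
    assemble_graph,
    degree_distribution,
    disease_shortest_paths,
    harmonize_ids,
    read_kg,
    write_kg,
)


def edge_df(rows):
    return pd.DataFrame(rows, columns=["source", "relation", "target"])


def map_df(pairs):
    return pd.DataFrame(pairs, columns=["from_id", "to_id"])


class TestKnowledgeGraph:
    def test_duplicate_triples_collapse(self):
        kg = KnowledgeGraph()
        kg.add_node("a", "gene")
        kg.add_node("b", "gene")
        kg.add_edge("a", "interacts_with", "b")
        kg.add_edge("a", "interacts_with", "b")
        assert kg.n_edges == 1

    def test_multi_relation_edges_kept(self):
        kg = KnowledgeGraph()
        kg.add_node("a", "gene")
        kg.add_node("b", "gene")
        kg.add_edge("a", "interacts_with", "b")
        kg.add_edge("a", "controls_expression_of", "b")
        assert kg.n_edges == 2
        assert len(kg.neighbors("a")) == 2

    def test_edge_requires_known_nodes(self):
        kg = KnowledgeGraph()
        kg.add_node("a", "gene")
        with pytest.raises(KeyError):
            kg.add_edge("a", "x", "ghost")

    def test_type_conflict_rejected(self):
        kg = KnowledgeGraph()
        kg.add_node("a", "gene")
        with pytest.raises(ValueError):
            kg.add_node("a", "disease")

    def test_tsv_roundtrip(self, tmp_path, small_synth):
        _, kg, _ = small_synth
        write_kg(kg, tmp_path / "n.tsv", tmp_path / "e.tsv")
        back = read_kg(tmp_path / "n.tsv", tmp_path / "e.tsv")
        assert dict(back.nodes) == dict(kg.nodes)
        assert back.edges == kg.edges


class TestHarmonizeIds:
    def test_single_hop(self):
        edges = edge_df([("CHEMBL:1", "targets", "G1")])
        out, report = harmonize_ids(edges, [map_df([("CHEMBL:1", "CHEBI:9")])])
        assert out.iloc[0]["source"] == "CHEBI:9"
        assert report["n_unmapped_ids"] == 1  # G1

    def test_transitive_chain(self):
        # transitive-closure oracle: CHEMBL:1 -> CHEBI:9 -> PUBCHEM:77
        edges = edge_df([("CHEMBL:1", "targets", "G1")])
        mappings = [
            map_df([("CHEMBL:1", "CHEBI:9")]),
            map_df([("CHEBI:9", "PUBCHEM:77")]),
        ]
        out, _ = harmonize_ids(edges, mappings)
        assert out.iloc[0]["source"] == "PUBCHEM:77"

    def test_unmapped_kept_and_reported(self):
        edges = edge_df([("X:1", "r", "Y:2")])
        out, report = harmonize_ids(edges, [map_df([("A:1", "B:1")])])
        assert list(out.iloc[0]) == ["X:1", "r", "Y:2"]
        assert set(report["unmapped_ids"]) == {"X:1", "Y:2"}

    def test_ambiguous_keeps_all(self):
        edges = edge_df([("A:1", "r", "G1")])
        out, report = harmonize_ids(
            edges, [map_df([("A:1", "B:1"), ("A:1", "B:2")])]
        )
        assert set(out["source"]) == {"B:1", "B:2"}
        assert "A:1" in report["ambiguous"]

    def test_circular_mapping_raises(self):
        edges = edge_df([("A:1", "r", "G1")])
        with pytest.raises(ValueError, match="circular"):
            harmonize_ids(edges, [map_df([("A:1", "B:1"), ("B:1", "A:1")])])


class TestAssembleGraph:
    def test_minimal_counts(self):
        ann = AnnotationSet(
            disease_to_genes={"d1": {"g1"}},
            disease_to_phenotypes={"d1": {"p1"}},
        )
        kg = assemble_graph(ann, OntologyDAG(), OntologyDAG())
        assert kg.n_nodes == 3
        assert kg.n_edges == 2

    def test_duplicate_input_triples_stored_once(self):
        ann = AnnotationSet(disease_to_genes={"d1": {"g1"}})
        inter = edge_df([("g1", "interacts_with", "g2")] * 3)
        kg = assemble_graph(
            ann, OntologyDAG(), OntologyDAG(), interaction_edges=inter
        )
        assert kg.n_edges == 2

    def test_untypable_edge_raises(self):
        ann = AnnotationSet(disease_to_genes={"d1": {"g1"}})
        with pytest.raises(ValueError, match="could not be typed"):
            assemble_graph(
                ann,
                OntologyDAG(),
                OntologyDAG(),
                gene_go_annotations={"g1": {"GO:404"}},
            )

    def test_no_direct_disease_disease_edges(self, small_synth):
        _, kg, _ = small_synth
        for s, _, t in kg.edges:
            assert not (
                kg.node_type(s) == "disease" and kg.node_type(t) == "disease"
            )

    def test_synthetic_counting_oracle(self, small_synth):
        # closed-form expectation from the generator config at noise 0
        config, kg, _ = small_synth
        c, d, g, p = 3, 10, 4, 6
        ont_terms = 7  # depth 2, branching 2
        assert len(kg.nodes_of_type("disease")) == c * d
        assert len(kg.nodes_of_type("gene")) == c * g
        assert len(kg.nodes_of_type("phenotype")) == c * p
        assert kg.n_nodes == c * (d + g + p) + 2 * ont_terms + 10
        rel = lambda r: sum(1 for _, x, _ in kg.edges if x == r)
        assert rel("has_gene") == c * d * g
        assert rel("has_phenotype") == c * d * p
        assert rel("is_a") == 2 * (ont_terms - 1)
        assert rel("annotated_to") == 2 * c * (g + p)  # 2 leaves each
        assert rel("interacts_with") <= c * g * (g - 1) // 2
        assert rel("activity") >= 10


class TestDegreeDistribution:
    def test_triangle(self):
        kg = KnowledgeGraph()
        for n in "abc":
            kg.add_node(n, "gene")
        kg.add_edge("a", "i", "b")
        kg.add_edge("b", "i", "c")
        kg.add_edge("c", "i", "a")
        assert degree_distribution(kg)["overall"] == {2: 3}

    def test_star(self):
        kg = KnowledgeGraph()
        kg.add_node("hub", "gene")
        for i in range(5):
            kg.add_node(f"l{i}", "phenotype")
            kg.add_edge("hub", "x", f"l{i}")
        hist = degree_distribution(kg)
        assert hist["overall"] == {5: 1, 1: 5}
        assert hist["per_type"]["gene"] == {5: 1}

    def test_per_type_partitions_overall(self, small_synth):
        _, kg, _ = small_synth
        hist = degree_distribution(kg)
        merged = {}
        for counts in hist["per_type"].values():
            for deg, n in counts.items():
                merged[deg] = merged.get(deg, 0) + n
        assert merged == hist["overall"]
        assert sum(hist["overall"].values()) == kg.n_nodes

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError):
            degree_distribution(KnowledgeGraph())


class TestDiseaseShortestPaths:
    def path_graph(self, chain, types):
        kg = KnowledgeGraph()
        for n, t in types.items():
            kg.add_node(n, t)
        for a, b in zip(chain, chain[1:]):
            kg.add_edge(a, "r", b)
        return kg

    def test_shared_gene_distance_two(self):
        kg = self.path_graph(
            ["d1", "g1", "d2"],
            {"d1": "disease", "g1": "gene", "d2": "disease"},
        )
        assert disease_shortest_paths(kg) == {
            "lengths": {2: 1},
            "unreachable_pairs": 0,
        }

    def test_phenotype_class_bridge_has_length_four(self):
        # disease - phenotype - ontology class - phenotype - disease
        kg = self.path_graph(
            ["d1", "p1", "h", "p2", "d2"],
            {
                "d1": "disease",
                "p1": "phenotype",
                "h": "hpo_term",
                "p2": "phenotype",
                "d2": "disease",
            },
        )
        assert disease_shortest_paths(kg)["lengths"] == {4: 1}

    def test_disconnected_pair_reported(self):
        kg = KnowledgeGraph()
        kg.add_node("d1", "disease")
        kg.add_node("d2", "disease")
        out = disease_shortest_paths(kg)
        assert out == {"lengths": {}, "unreachable_pairs": 1}

    def test_requires_two_diseases(self):
        kg = KnowledgeGraph()
        kg.add_node("d1", "disease")
        with pytest.raises(ValueError):
            disease_shortest_paths(kg)

    def test_agrees_with_networkx_bfs_oracle(self, small_synth):
        _, kg, _ = small_synth
        g = nx.Graph()
        g.add_nodes_from(kg.nodes)
        g.add_edges_from((s, t) for s, _, t in kg.edges)
        diseases = kg.nodes_of_type("disease")
        expected = {}
        for i, a in enumerate(diseases):
            sp = nx.single_source_shortest_path_length(g, a)
            for b in diseases[i + 1 :]:
                if b in sp:
                    expected[sp[b]] = expected.get(sp[b], 0) + 1
        assert disease_shortest_paths(kg)["lengths"] == expected
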