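import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from rdkg import (
    AnnotationSet,
    WalkCorpus,
    bh_fdr,
    gene_cluster_counts,
    permutation_enrichment,
    summarize_by_percentile,
    summarize_drug_connections,
    tfidf_features,
)


def three_cluster_annotations():
    """30 diseases in 3 equal clusters; gene gX annotated to all of cluster 0."""
    labels = {f"d{i}": i // 10 for i in range(30)}
    ann = AnnotationSet()
    for i in range(10):
        ann.disease_to_genes[f"d{i}"] = {"gX"}
    return ann, labels


class TestGeneClusterCounts:
    def test_two_diseases_same_cluster(self):
        ann = AnnotationSet(disease_to_genes={"d1": {"g"}, "d2": {"g"}})
        labels = {"d1": 0, "d2": 0, "d3": 1}
        assert gene_cluster_counts(ann, labels) == {("g", 0): 2}

    def test_row_sums_equal_annotation_counts(self, small_synth):
        _, kg, truth = small_synth
        ann = AnnotationSet.from_kg(kg)
        counts = gene_cluster_counts(ann, truth.disease_labels)
        per_gene = Counter()
        for (g, _), n in counts.items():
            per_gene[g] += n
        expected = Counter()
        for genes in ann.disease_to_genes.values():
            for g in genes:
                expected[g] += 1
        assert per_gene == expected

    def test_unlabeled_disease_rejected(self):
        ann = AnnotationSet(disease_to_genes={"d1": {"g"}})
        with pytest.raises(ValueError, match="without a cluster label"):
            gene_cluster_counts(ann, {"other": 0})


class TestPermutationEnrichment:
    def test_ubiquitous_gene_has_p_one(self):
        # a gene annotated to every disease keeps its count under any
        # permutation, so no permutation count can fall below the observed
        labels = {f"d{i}": i % 3 for i in range(12)}
        ann = AnnotationSet(
            disease_to_genes={d: {"everywhere"} for d in labels}
        )
        table = permutation_enrichment(ann, labels, B=200, seed=0)
        assert (table["p_value"] == 1.0).all()

    def test_perfectly_concentrated_gene_hits_floor(self):
        # hypergeometric oracle: P(permuted count = 10) = 1/C(30,10) ~ 3e-8,
        # so with B=2000 no permutation matches and p = 1/(B+1)
        ann, labels = three_cluster_annotations()
        B = 2000
        table = permutation_enrichment(ann, labels, B=B, seed=1)
        row = table[(table["gene"] == "gX") & (table["cluster"] == 0)].iloc[0]
        assert row["observed_count"] == 10
        assert row["p_value"] == pytest.approx(1 / (B + 1))

    def test_only_observed_pairs_tested(self):
        ann, labels = three_cluster_annotations()
        table = permutation_enrichment(ann, labels, B=50, seed=0)
        assert set(zip(table["gene"], table["cluster"])) == {("gX", 0)}

    def test_deterministic(self):
        ann, labels = three_cluster_annotations()
        a = permutation_enrichment(ann, labels, B=500, seed=3)
        b = permutation_enrichment(ann, labels, B=500, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_b_rejected(self):
        ann, labels = three_cluster_annotations()
        with pytest.raises(ValueError):
            permutation_enrichment(ann, labels, B=0, seed=0)

    def test_single_cluster_rejected(self):
        ann = AnnotationSet(disease_to_genes={"d1": {"g"}})
        with pytest.raises(ValueError):
            permutation_enrichment(ann, {"d1": 0}, B=10, seed=0)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03]) == [pytest.approx(0.03)]

    def test_hand_computed_triple(self):
        # q_i = p_i * n / rank_i then monotone: (0.03, 0.03, 0.03)
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])

    def test_never_below_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, 50).tolist()
        q = bh_fdr(p)
        assert all(qi >= pi - 1e-12 for pi, qi in zip(p, q))


def brute_force_tfidf(walks, labels, window):
    """Independent naive oracle: per-occurrence window counting."""
    clusters = sorted(set(labels.values()))
    tf = {c: Counter() for c in clusters}
    for walk in walks:
        for i, tok in enumerate(walk):
            if tok in labels:
                c = labels[tok]
                lo, hi = max(0, i - window), min(len(walk), i + window + 1)
                for j in range(lo, hi):
                    if j != i:
                        tf[c][walk[j]] += 1
    rows = []
    for c in clusters:
        for feature, count in tf[c].items():
            df = sum(1 for cc in clusters if tf[cc][feature] > 0)
            rows.append(
                (c, feature, count, df, count * math.log(len(clusters) / df))
            )
    return {
        (c, f): (t, d, x) for c, f, t, d, x in rows
    }


class TestTfidfFeatures:
    def toy_corpus(self):
        walks = [
            ["D1", "has_gene", "G1", "annotated_to", "T1", "is_a", "T2"],
            ["D2", "has_gene", "G1", "interacts_with", "G2", "has_gene", "D1"],
            ["D3", "has_phenotype", "P1", "annotated_to", "T2"],
        ]
        labels = {"D1": 0, "D2": 0, "D3": 1}
        return WalkCorpus(walks), labels

    def test_matches_brute_force_oracle(self):
        corpus, labels = self.toy_corpus()
        for window in (1, 2, 3, 10):
            got = tfidf_features(corpus, labels, window=window)
            expected = brute_force_tfidf(corpus.walks, labels, window)
            assert len(got) == len(expected)
            for _, row in got.iterrows():
                tf, df, tfidf = expected[(row["cluster"], row["feature"])]
                assert row["tf"] == tf
                assert row["df"] == df
                assert row["tfidf"] == pytest.approx(tfidf, abs=1e-12)

    def test_matches_oracle_on_synthetic_corpus(self, small_synth):
        from rdkg import WalkParams, generate_walks

        _, kg, truth = small_synth
        corpus = generate_walks(kg, WalkParams(3, 8, seed=9))
        assert len(corpus.walks) <= 100
        got = tfidf_features(
            corpus, truth.disease_labels, window=5, node_types=kg.nodes
        )
        expected = brute_force_tfidf(corpus.walks, truth.disease_labels, 5)
        assert len(got) == len(expected)
        for _, row in got.iterrows():
            tf, df, tfidf = expected[(row["cluster"], row["feature"])]
            assert (row["tf"], row["df"]) == (tf, df)
            assert row["tfidf"] == pytest.approx(tfidf, abs=1e-12)

    def test_feature_in_all_clusters_scores_zero(self):
        walks = [["D1", "r", "X"], ["D2", "r", "X"]]
        labels = {"D1": 0, "D2": 1}
        table = tfidf_features(WalkCorpus(walks), labels, window=2)
        x_rows = table[table["feature"] == "X"]
        assert (x_rows["tfidf"] == 0.0).all()

    def test_exclusive_feature_scores_tf_ln_n(self):
        # tf=5 in exactly 1 of 4 clusters -> tfidf = 5 ln 4
        walks = [["D1"] + ["r", "U"] * 5]
        walks += [[f"D{i}", "r", f"V{i}"] for i in (2, 3, 4)]
        labels = {f"D{i}": i - 1 for i in (1, 2, 3, 4)}
        table = tfidf_features(WalkCorpus(walks), labels, window=10)
        row = table[(table["feature"] == "U") & (table["cluster"] == 0)].iloc[0]
        assert row["tf"] == 5
        assert row["tfidf"] == pytest.approx(5 * math.log(4), abs=1e-12)

    def test_unlabeled_corpus_disease_rejected(self):
        walks = [["D1", "r", "X"]]
        with pytest.raises(ValueError, match="without a label"):
            tfidf_features(WalkCorpus(walks), {"D2": 0}, window=2)

    def test_feature_types_from_node_map(self):
        walks = [["D1", "has_gene", "G1"]]
        table = tfidf_features(
            WalkCorpus(walks),
            {"D1": 0},
            window=2,
            node_types={"D1": "disease", "G1": "gene"},
        )
        types = dict(zip(table["feature"], table["feature_type"]))
        assert types == {"G1": "gene", "has_gene": "relation"}


class TestSummarizeByPercentile:
    def make_summary(self):
        walks = [
            ["D1", "r", "A", "r", "A", "r", "B"],
            ["D2", "r", "B", "r", "C"],
        ]
        labels = {"D1": 0, "D2": 1}
        return tfidf_features(WalkCorpus(walks), labels, window=6)

    def test_threshold_zero_counts_everything(self):
        summary = self.make_summary()
        out = summarize_by_percentile(summary, [0.0])
        totals = summary.groupby(["cluster", "feature_type"]).size()
        for _, row in out.iterrows():
            assert row["n_features"] == totals[(row["cluster"], row["feature_type"])]

    def test_counts_nonincreasing_in_threshold(self):
        out = summarize_by_percentile(self.make_summary(), [0, 50, 90, 100])
        for _, group in out.groupby(["cluster", "feature_type"]):
            ordered = group.sort_values("threshold")["n_features"].tolist()
            assert ordered == sorted(ordered, reverse=True)

    def test_threshold_100_keeps_only_maximal(self):
        summary = self.make_summary()
        out = summarize_by_percentile(summary, [100.0])
        max_val = summary["tfidf"].max()
        n_max_total = int((summary["tfidf"] == max_val).sum())
        assert out["n_features"].sum() == n_max_total

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            summarize_by_percentile(self.make_summary(), [120])


class TestSummarizeDrugConnections:
    def fixture(self):
        ann = AnnotationSet(
            disease_to_genes={
                "d1": {"g1", "g2"},
                "d2": {"g2"},
                "d3": {"g3"},
            }
        )
        labels = {"d1": 0, "d2": 1, "d3": 1}
        activity = pd.DataFrame(
            {
                "target": ["g1", "g2", "g3"],
                "ligand": ["drugA", "drugA", "ligB"],
                "is_approved_drug": [True, True, False],
                "tdl": ["Tclin", "Tclin", "Tbio"],
            }
        )
        return activity, ann, labels

    def test_drug_hitting_two_targets_counted_once(self):
        activity, ann, labels = self.fixture()
        _, drugs = summarize_drug_connections(activity, ann, labels)
        per_cluster = dict(zip(drugs["cluster"], drugs["n_approved_drugs"]))
        assert per_cluster[0] == 1  # drugA via g1 and g2, deduplicated

    def test_target_spanning_clusters_counted_in_both(self):
        activity, ann, labels = self.fixture()
        tdl, _ = summarize_drug_connections(activity, ann, labels)
        tclin = tdl[tdl["tdl"] == "Tclin"].set_index("cluster")["n_targets"]
        assert tclin[0] == 2  # g1 and g2
        assert tclin[1] == 1  # g2 through d2

    def test_cluster_without_targets_has_zero_drugs(self):
        activity, ann, labels = self.fixture()
        labels = {**labels, "d4": 2}
        ann.disease_to_genes["d4"] = {"unlisted_gene"}
        _, drugs = summarize_drug_connections(activity, ann, labels)
        per_cluster = dict(zip(drugs["cluster"], drugs["n_approved_drugs"]))
        assert per_cluster[2] == 0

    def test_unknown_tdl_rejected(self):
        activity, ann, labels = self.fixture()
        activity.loc[0, "tdl"] = "Tmystery"
        with pytest.raises(ValueError, match="Tmystery"):
            summarize_drug_connections(activity, ann, labels)
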