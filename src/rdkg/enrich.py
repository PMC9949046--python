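"""Cluster interpretation: permutation gene enrichment, tf-idf walk
features, percentile summaries and drug-connection counts.

The gene enrichment test asks, for every (gene, cluster) pair with at least
one observed annotation, whether the gene's diseases concentrate in the
cluster more than expected if diseases were assigned to clusters at random.
The null is generated by permuting the disease->cluster assignment while
holding the disease->gene annotations fixed; the p-value uses the standard
add-one permutation correction, p = (1 + #{permutations with count >=
observed}) / (B + 1), so p is never 0 and Benjamini-Hochberg FDR control is
well defined.

tf-idf treats each cluster as a "document" whose terms are the tokens seen
inside a window around every occurrence of the cluster's diseases in the
walk corpus; idf = ln(N_clusters / #clusters containing the feature), base
e, no smoothing.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.stats.multitest import multipletests

from .graph import AnnotationSet
from .walks import WalkCorpus

__all__ = [
    "gene_cluster_counts",
    "permutation_enrichment",
    "bh_fdr",
    "tfidf_features",
    "summarize_by_percentile",
    "summarize_drug_connections",
    "TDL_LEVELS",
]

TDL_LEVELS = frozenset({"Tclin", "Tchem", "Tbio", "Tdark"})


def _check_labels_cover(annotated: set[str], labels: Mapping[str, int]) -> None:
    missing = sorted(annotated - set(labels))
    if missing:
        raise ValueError(f"annotated diseases without a cluster label: {missing[:10]}")


def gene_cluster_counts(
    annotations: AnnotationSet, labels: Mapping[str, int]
) -> dict[tuple[str, int], int]:
    """count(g, c) = number of diseases in cluster c annotated to gene g."""
    _check_labels_cover(set(annotations.disease_to_genes), labels)
    counts: Counter[tuple[str, int]] = Counter()
    for disease, genes in annotations.disease_to_genes.items():
        c = labels[disease]
        for g in genes:
            counts[(g, c)] += 1
    return dict(counts)


def _annotation_matrix(
    annotations: AnnotationSet, labels: Mapping[str, int]
) -> tuple[sp.csr_matrix, list[str], list[str], np.ndarray, list[int]]:
    genes = sorted({g for gs in annotations.disease_to_genes.values() for g in gs})
    diseases = sorted(labels)
    d_index = {d: i for i, d in enumerate(diseases)}
    g_index = {g: i for i, g in enumerate(genes)}
    rows, cols = [], []
    for d, gs in annotations.disease_to_genes.items():
        for g in gs:
            rows.append(g_index[g])
            cols.append(d_index[d])
    A = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.float32), (rows, cols)),
        shape=(len(genes), len(diseases)),
    )
    clusters = sorted(set(labels.values()))
    c_index = {c: i for i, c in enumerate(clusters)}
    lab = np.array([c_index[labels[d]] for d in diseases])
    return A, genes, diseases, lab, clusters


def permutation_enrichment(
    annotations: AnnotationSet,
    labels: Mapping[str, int],
    B: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-null gene enrichment per (gene, cluster) pair.

    Only pairs with observed_count >= 1 are tested; q-values are
    Benjamini-Hochberg over that family.  Columns: gene, cluster,
    observed_count, p_value, q_value.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    _check_labels_cover(set(annotations.disease_to_genes), labels)
    if len(set(labels.values())) < 2:
        raise ValueError("need at least two clusters")
    A, genes, _, lab, clusters = _annotation_matrix(annotations, labels)
    K = len(clusters)
    onehot = np.zeros((lab.size, K), dtype=np.float32)
    onehot[np.arange(lab.size), lab] = 1.0
    observed = np.asarray(A @ onehot)  # genes x clusters

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed, dtype=np.int64)
    chunk = max(1, min(256, B))
    done = 0
    n_dis = lab.size
    rows_idx = np.arange(n_dis)
    while done < B:
        c = min(chunk, B - done)
        block = np.zeros((n_dis, K * c), dtype=np.float32)
        for j in range(c):
            perm = rng.permutation(lab)
            block[rows_idx, perm + j * K] = 1.0
        counts = np.asarray(A @ block).reshape(observed.shape[0], c, K)
        exceed += (counts >= observed[:, None, :]).sum(axis=1)
        done += c

    tested = observed >= 1
    p = (1.0 + exceed[tested]) / (B + 1.0)
    gi, ci = np.nonzero(tested)
    out = pd.DataFrame(
        {
            "gene": [genes[i] for i in gi],
            "cluster": [clusters[j] for j in ci],
            "observed_count": observed[tested].astype(int),
            "p_value": p,
        }
    )
    out["q_value"] = bh_fdr(out["p_value"].tolist())
    return out.sort_values(["gene", "cluster"], ignore_index=True)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def tfidf_features(
    corpus: WalkCorpus,
    labels: Mapping[str, int],
    window: int,
    node_types: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """tf-idf of walk-window features per cluster.

    For every occurrence of a labeled disease token in any walk, the tokens
    within ``window`` positions on either side (truncated at walk ends,
    excluding the occurrence itself) are counted toward the disease's
    cluster.  Windows around nearby occurrences may overlap and then
    double-count tokens.  df(feature) = number of clusters where the
    feature appears at all; tfidf = tf * ln(N_clusters / df).  The
    percentile column is the pooled empirical CDF of the tfidf values, in
    [0, 100].  Feature type is looked up in ``node_types``; tokens not in
    the map (edge relation labels) get type "relation".
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    clusters = sorted(set(labels.values()))
    n_clusters = len(clusters)
    c_index = {c: i for i, c in enumerate(clusters)}

    vocab = sorted({tok for walk in corpus.walks for tok in walk})
    index = {tok: i for i, tok in enumerate(vocab)}
    V = len(vocab)
    label_code = np.full(V, -1, dtype=np.int64)
    for tok, c in labels.items():
        if tok in index:
            label_code[index[tok]] = c_index[c]
    if node_types:
        untracked = sorted(
            tok
            for tok in vocab
            if node_types.get(tok) == "disease" and tok not in labels
        )
        if untracked:
            raise ValueError(f"corpus diseases without labels: {untracked[:10]}")
    for walk in corpus.walks:
        if walk and walk[0] not in labels:
            raise ValueError(f"corpus disease without a label: {walk[0]!r}")

    tf = np.zeros((n_clusters, V), dtype=np.int64)
    walk_arrays = [
        np.fromiter((index[t] for t in walk), dtype=np.int64, count=len(walk))
        for walk in corpus.walks
    ]
    codes = np.concatenate(walk_arrays) if walk_arrays else np.empty(0, np.int64)
    walk_id = np.concatenate(
        [np.full(a.size, i, dtype=np.int64) for i, a in enumerate(walk_arrays)]
    ) if walk_arrays else np.empty(0, np.int64)
    centers = label_code[codes]  # cluster of each position, -1 if not a disease
    for off in range(1, window + 1):
        for lo_c, lo_f in ((slice(None, -off), slice(off, None)),
                           (slice(off, None), slice(None, -off))):
            if codes.size <= off:
                continue
            c_part = centers[lo_c]
            f_part = codes[lo_f]
            same_walk = walk_id[lo_c] == walk_id[lo_f]
            mask = (c_part >= 0) & same_walk
            if not np.any(mask):
                continue
            np.add.at(tf, (c_part[mask], f_part[mask]), 1)

    df_counts = (tf > 0).sum(axis=0)
    rows = []
    for ci, c in enumerate(clusters):
        present = np.nonzero(tf[ci])[0]
        for vi in present:
            tok = vocab[vi]
            tfidf = tf[ci, vi] * np.log(n_clusters / df_counts[vi])
            ftype = (node_types or {}).get(tok, "relation")
            rows.append(
                {
                    "cluster": c,
                    "feature": tok,
                    "feature_type": ftype,
                    "tf": int(tf[ci, vi]),
                    "df": int(df_counts[vi]),
                    "tfidf": float(tfidf),
                }
            )
    out = pd.DataFrame(
        rows, columns=["cluster", "feature", "feature_type", "tf", "df", "tfidf"]
    )
    if len(out):
        vals = np.sort(out["tfidf"].to_numpy())
        out["percentile"] = (
            np.searchsorted(vals, out["tfidf"].to_numpy(), side="right")
            / len(vals)
            * 100.0
        )
    else:
        out["percentile"] = pd.Series(dtype=float)
    return out.sort_values(["cluster", "feature"], ignore_index=True)


def summarize_by_percentile(
    summary: pd.DataFrame, thresholds: Sequence[float]
) -> pd.DataFrame:
    """Count features at or above each tf-idf percentile threshold,
    per cluster and feature type."""
    for t in thresholds:
        if not 0 <= t <= 100:
            raise ValueError("thresholds must lie in [0, 100]")
    rows = []
    for (cluster, ftype), group in summary.groupby(
        ["cluster", "feature_type"], sort=True
    ):
        for t in thresholds:
            rows.append(
                {
                    "cluster": cluster,
                    "feature_type": ftype,
                    "threshold": t,
                    "n_features": int((group["percentile"] >= t).sum()),
                }
            )
    return pd.DataFrame(rows)


def summarize_drug_connections(
    activity_table: pd.DataFrame,
    annotations: AnnotationSet,
    labels: Mapping[str, int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster druggability summary from a Pharos-style activity table.

    A gene target counts toward a cluster when it is annotated to at least
    one disease of that cluster (a target annotated across clusters counts
    in each).  Drugs are unique approved ligand ids over a cluster's
    targets.  Returns (targets-by-TDL table, drugs-per-cluster table).
    """
    bad = sorted(set(activity_table["tdl"]) - TDL_LEVELS)
    if bad:
        raise ValueError(f"unknown TDL labels: {bad}")
    _check_labels_cover(set(annotations.disease_to_genes), labels)
    gene_clusters: dict[str, set[int]] = {}
    for d, genes in annotations.disease_to_genes.items():
        for g in genes:
            gene_clusters.setdefault(g, set()).add(labels[d])
    clusters = sorted(set(labels.values()))

    tdl_of = dict(zip(activity_table["target"], activity_table["tdl"]))
    tdl_rows = []
    drug_rows = []
    for c in clusters:
        targets = sorted(
            g for g, cs in gene_clusters.items() if c in cs and g in tdl_of
        )
        tdl_counts = Counter(tdl_of[g] for g in targets)
        for level in sorted(TDL_LEVELS):
            tdl_rows.append(
                {"cluster": c, "tdl": level, "n_targets": tdl_counts.get(level, 0)}
            )
        in_cluster = activity_table["target"].isin(targets)
        approved = activity_table.loc[
            in_cluster & activity_table["is_approved_drug"], "ligand"
        ]
        drug_rows.append({"cluster": c, "n_approved_drugs": int(approved.nunique())})
    return pd.DataFrame(tdl_rows), pd.DataFrame(drug_rows)
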