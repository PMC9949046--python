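"""Skip-gram node embeddings from the walk corpus.

The trainer is an explicit-matrix skip-gram: token co-occurrence counts are
collected inside a symmetric window over every walk, converted to shifted
positive pointwise mutual information (the matrix that skip-gram with
negative sampling implicitly factorizes; the shift is ln of the
negative-sample count), and factorized with a truncated SVD.  The embedding
of token *w* is ``U_w * sqrt(sigma)``.  This formulation is deterministic
under a fixed seed and single-threaded by construction, which matters
because downstream cluster labels must be exactly reproducible.

Also houses the two dimension-selection aids used to pick the embedding
width: the fourth-root-of-vocabulary heuristic and the PCA explained-
variance profile of a trained embedding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA, TruncatedSVD

from .walks import WalkCorpus

__all__ = [
    "EmbedParams",
    "EmbeddingMatrix",
    "train_embedding",
    "suggest_dimension",
    "pca_variance_profile",
]


@dataclass(frozen=True)
class EmbedParams:
    """dimension: embedding width; window: context size in tokens (edge-label
    tokens count); negative: PPMI shift, the analogue of the negative-sample
    count; min_count: 0 by default so rare diseases are never dropped."""

    dimension: int = 32
    window: int = 20
    min_count: int = 0
    negative: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension < 1 or self.window < 1:
            raise ValueError("dimension and window must be >= 1")
        if self.min_count < 0 or self.negative < 1:
            raise ValueError("min_count must be >= 0 and negative >= 1")


@dataclass
class EmbeddingMatrix:
    disease_ids: list[str]
    vectors: np.ndarray  # shape (n_diseases, dimension)

    def __post_init__(self) -> None:
        if len(self.disease_ids) != self.vectors.shape[0]:
            raise ValueError("row count does not match disease_ids")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease ids")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding entries")

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"v{i}" for i in range(self.dimension)]
        df = pd.DataFrame(self.vectors, columns=cols)
        df.insert(0, "disease_id", self.disease_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EmbeddingMatrix":
        df = pd.read_csv(path)
        ids = df["disease_id"].astype(str).tolist()
        return cls(ids, df.drop(columns="disease_id").to_numpy(dtype=float))


def _cooccurrence(encoded: list[np.ndarray], vocab_size: int, window: int) -> sp.csr_matrix:
    """Symmetric windowed co-occurrence counts over all walks."""
    dense_ok = vocab_size * vocab_size <= 20_000_000
    if dense_ok:
        flat = np.zeros(vocab_size * vocab_size, dtype=np.int64)
    else:
        acc = sp.csr_matrix((vocab_size, vocab_size), dtype=np.int64)
    for offset in range(1, window + 1):
        rows_parts, cols_parts = [], []
        for arr in encoded:
            if arr.size > offset:
                rows_parts.append(arr[:-offset])
                cols_parts.append(arr[offset:])
        if not rows_parts:
            continue
        rows = np.concatenate(rows_parts).astype(np.int64)
        cols = np.concatenate(cols_parts).astype(np.int64)
        if dense_ok:
            flat += np.bincount(
                rows * vocab_size + cols, minlength=vocab_size * vocab_size
            )
            flat += np.bincount(
                cols * vocab_size + rows, minlength=vocab_size * vocab_size
            )
        else:
            part = sp.coo_matrix(
                (np.ones(rows.size, dtype=np.int64), (rows, cols)),
                shape=(vocab_size, vocab_size),
            ).tocsr()
            acc = acc + part + part.T
    if dense_ok:
        mat = flat.reshape(vocab_size, vocab_size)
        return sp.csr_matrix(mat)
    return acc


def _sppmi(counts: sp.csr_matrix, shift: float) -> sp.csr_matrix:
    total = counts.sum()
    row = np.asarray(counts.sum(axis=1)).ravel()
    col = np.asarray(counts.sum(axis=0)).ravel()
    coo = counts.tocoo()
    with np.errstate(divide="ignore"):
        pmi = np.log(coo.data.astype(float) * total) - np.log(
            row[coo.row] * col[coo.col]
        )
    data = np.maximum(pmi - math.log(shift), 0.0)
    out = sp.coo_matrix((data, (coo.row, coo.col)), shape=counts.shape).tocsr()
    out.eliminate_zeros()
    return out


def train_embedding(corpus: WalkCorpus, params: EmbedParams) -> EmbeddingMatrix:
    """Train skip-gram embeddings and extract the disease rows.

    Disease tokens are identified as the first token of each walk (every
    walk starts at a disease).  Vectors for non-disease tokens are computed
    internally but only the disease matrix is returned.  Raises if any
    disease token occurs fewer than ``min_count`` times in the corpus.
    """
    walks = corpus.walks
    if not walks:
        raise ValueError("empty corpus")
    vocab = sorted({tok for walk in walks for tok in walk})
    index = {tok: i for i, tok in enumerate(vocab)}
    disease_ids = sorted({walk[0] for walk in walks})

    if params.min_count > 0:
        counts: dict[str, int] = {d: 0 for d in disease_ids}
        for walk in walks:
            for tok in walk:
                if tok in counts:
                    counts[tok] += 1
        missing = sorted(d for d, c in counts.items() if c < params.min_count)
        if missing:
            raise ValueError(
                f"diseases below min_count={params.min_count}: {missing}"
            )

    encoded = [
        np.fromiter((index[t] for t in walk), dtype=np.int32, count=len(walk))
        for walk in walks
    ]
    cooc = _cooccurrence(encoded, len(vocab), params.window)
    ppmi = _sppmi(cooc, float(params.negative))

    n_components = min(params.dimension, len(vocab) - 1)
    if n_components < 1:
        all_vectors = np.zeros((len(vocab), params.dimension))
    else:
        svd = TruncatedSVD(n_components=n_components, random_state=params.seed)
        transformed = svd.fit_transform(ppmi)  # U * sigma
        sigma = svd.singular_values_
        scale = np.where(sigma > 0, np.sqrt(np.maximum(sigma, 0.0)), 1.0)
        u_sqrt_sigma = transformed / scale  # U * sqrt(sigma)
        all_vectors = np.zeros((len(vocab), params.dimension))
        all_vectors[:, :n_components] = u_sqrt_sigma

    rows = np.array([index[d] for d in disease_ids])
    return EmbeddingMatrix(disease_ids, all_vectors[rows])


def suggest_dimension(vocab_size: int) -> int:
    """Fourth-root heuristic: round-half-up of vocab_size**(1/4), minimum 1.

    "Vocabulary" is the count of unique tokens in the walk corpus — unique
    nodes plus unique edge labels traversed.
    """
    if vocab_size < 1:
        raise ValueError("vocab_size must be a positive integer")
    return max(1, math.floor(vocab_size**0.25 + 0.5))


def pca_variance_profile(emb: EmbeddingMatrix) -> list[float]:
    """Explained-variance fractions of the disease embedding, nonincreasing
    and summing to 1.  A flat profile means the embedding width cannot be
    reduced; a sharp drop-off means it can."""
    if len(emb.disease_ids) < 2:
        raise ValueError("need at least two diseases")
    centered = emb.vectors - emb.vectors.mean(axis=0)
    if not np.any(np.abs(centered) > 1e-12):
        raise ValueError("constant embedding matrix has no variance to explain")
    pca = PCA(svd_solver="full")
    pca.fit(emb.vectors)
    return [float(f) for f in pca.explained_variance_ratio_]
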