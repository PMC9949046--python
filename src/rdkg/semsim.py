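"""Intrinsic information-content semantic similarity for cluster validation.

The Sanchez information content of a term c in an is_a hierarchy is

    IC(c) = -ln( (|leaves(c)| / |subsumers(c)| + 1) / (max_leaves + 1) )

where leaves(c) are the leaf descendants of c (c itself when c is a leaf),
subsumers(c) the ancestors of c including c, and max_leaves the total leaf
count of the ontology.  IC needs no corpus, only the hierarchy: generic
terms (many leaves, few subsumers) score near 0, specific terms score high.
Pairwise similarity combines IC in the Lin form,

    sim(a, b) = 2 * IC(MICA(a, b)) / (IC(a) + IC(b))  in [0, 1],

with MICA the common ancestor of maximal IC.  Cluster validation compares
the mean pairwise similarity within each disease cluster against random
disease sets of matched size drawn from the same ontology, via a one-sample
t-test of the cluster means against the null mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .ontology import OntologyDAG

__all__ = [
    "SemSimReport",
    "sanchez_ic",
    "pairwise_similarity",
    "cluster_semsim",
    "null_semsim",
    "semsim_t_test",
]

logger = logging.getLogger(__name__)


@dataclass
class SemSimReport:
    cluster_means: dict[int, float]
    null_means: list[float]
    n_sets: int
    set_size: int
    t_statistic: float
    p_value: float
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cluster_means": {str(k): v for k, v in self.cluster_means.items()},
            "null_means": list(self.null_means),
            "n_sets": self.n_sets,
            "set_size": self.set_size,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            **self.extra,
        }


def _cache(ont: OntologyDAG) -> dict:
    """Ancestor sets, leaf-descendant counts and ICs, memoized per ontology."""
    cache = getattr(ont, "_semsim_cache", None)
    if cache is not None:
        return cache
    leaves = ont.leaves
    anc = {t: frozenset(ont.ancestors(t, include_self=True)) for t in ont.terms}
    n_leaf_desc = {
        t: (1 if t in leaves else len(ont.descendants(t) & leaves))
        for t in ont.terms
    }
    max_leaves = len(leaves)
    ic = {
        t: abs(-math.log((n_leaf_desc[t] / len(anc[t]) + 1.0) / (max_leaves + 1.0)))
        for t in ont.terms
    }
    cache = {"anc": anc, "ic": ic, "max_leaves": max_leaves}
    ont._semsim_cache = cache
    return cache


def sanchez_ic(ont: OntologyDAG, term: str) -> float:
    """Sanchez intrinsic information content; 0 for any root of a tree."""
    if term not in ont:
        raise KeyError(f"unknown ontology term: {term!r}")
    return _cache(ont)["ic"][term]


def _mica_ic(cache: dict, a: str, b: str) -> float:
    common = cache["anc"][a] & cache["anc"][b]
    if not common:
        return 0.0
    ic = cache["ic"]
    return max(ic[t] for t in common)


def pairwise_similarity(ont: OntologyDAG, a: str, b: str) -> float:
    """Lin similarity with the most-informative common ancestor."""
    for t in (a, b):
        if t not in ont:
            raise KeyError(f"unknown ontology term: {t!r}")
    cache = _cache(ont)
    ica, icb = cache["ic"][a], cache["ic"][b]
    if ica + icb == 0.0:
        return 0.0
    if a == b:
        return 1.0
    return min(1.0, 2.0 * _mica_ic(cache, a, b) / (ica + icb))


def _mean_pairwise(
    cache: dict, members: Sequence[str], pair_memo: dict | None = None
) -> float:
    ic = cache["ic"]
    total = 0.0
    n = 0
    for a, b in combinations(members, 2):
        key = (a, b) if a <= b else (b, a)
        if pair_memo is not None and key in pair_memo:
            sim = pair_memo[key]
        else:
            denom = ic[a] + ic[b]
            sim = 0.0 if denom == 0.0 else min(1.0, 2.0 * _mica_ic(cache, a, b) / denom)
            if pair_memo is not None:
                pair_memo[key] = sim
        total += sim
        n += 1
    return total / n


def cluster_semsim(
    ont: OntologyDAG, labels: Mapping[str, int]
) -> dict[int, float]:
    """Mean within-cluster pairwise similarity per cluster.

    Diseases absent from the ontology are dropped (with a logged count);
    clusters left with fewer than two resolvable diseases are reported as
    missing (omitted from the map), never as zero.
    """
    cache = _cache(ont)
    dropped = [d for d in labels if d not in ont]
    if dropped:
        logger.warning(
            "%d diseases absent from the validation ontology were dropped",
            len(dropped),
        )
    by_cluster: dict[int, list[str]] = {}
    for d, c in labels.items():
        if d in ont:
            by_cluster.setdefault(c, []).append(d)
    memo: dict = {}
    out: dict[int, float] = {}
    for c, members in sorted(by_cluster.items()):
        if len(members) < 2:
            logger.warning("cluster %s has < 2 resolvable diseases; skipped", c)
            continue
        out[c] = _mean_pairwise(cache, sorted(members), memo)
    return out


def null_semsim(
    ont: OntologyDAG,
    disease_pool: Sequence[str],
    n_sets: int,
    set_size: int,
    seed: int = 0,
) -> list[float]:
    """Mean pairwise similarity of ``n_sets`` random disease sets.

    Each set is a uniform sample of ``set_size`` diseases without
    replacement from the pool; together the set means form the sampling
    distribution of within-set similarity under random grouping.
    """
    pool = sorted(set(disease_pool))
    if set_size > len(pool):
        raise ValueError(f"set_size={set_size} exceeds pool size {len(pool)}")
    if set_size < 2 or n_sets < 1:
        raise ValueError("need set_size >= 2 and n_sets >= 1")
    for d in pool:
        if d not in ont:
            raise KeyError(f"disease {d!r} absent from the ontology")
    cache = _cache(ont)
    rng = np.random.default_rng(seed)
    memo: dict = {}
    means = []
    for _ in range(n_sets):
        members = [pool[i] for i in rng.choice(len(pool), set_size, replace=False)]
        means.append(_mean_pairwise(cache, members, memo))
    return means


def semsim_t_test(
    cluster_means: Mapping[int, float],
    null_means: Sequence[float],
    n_sets: int | None = None,
    set_size: int | None = None,
    use_null_variance: bool = False,
) -> tuple[float, float, SemSimReport]:
    """One-sample test of the cluster means against the random-set mean.

    Default: Student's t of the cluster means against mu0 = mean(null_means),
    two-sided, n_clusters - 1 degrees of freedom.  With
    ``use_null_variance=True`` a z-form is used instead, scaling by the
    standard deviation of the null set means (normal two-sided p).
    """
    values = np.array([cluster_means[c] for c in sorted(cluster_means)], dtype=float)
    null = np.asarray(list(null_means), dtype=float)
    if values.size < 2 or null.size < 2:
        raise ValueError("need >= 2 cluster means and >= 2 null means")
    mu0 = float(null.mean())
    if use_null_variance:
        sd = float(null.std(ddof=1))
        if sd == 0.0:
            raise ValueError("zero variance in null means")
        t = (float(values.mean()) - mu0) / sd
        p = float(2.0 * stats.norm.sf(abs(t)))
    elif float(values.std(ddof=1)) == 0.0:
        # Degenerate but well-defined when the means sit exactly on mu0.
        if float(values.mean()) == mu0:
            t, p = 0.0, 1.0
        else:
            raise ValueError("zero variance in cluster means")
    else:
        res = stats.ttest_1samp(values, popmean=mu0)
        t, p = float(res.statistic), float(res.pvalue)
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    report = SemSimReport(
        cluster_means=dict(cluster_means),
        null_means=[float(v) for v in null],
        n_sets=n_sets if n_sets is not None else int(null.size),
        set_size=set_size if set_size is not None else -1,
        t_statistic=t,
        p_value=p,
    )
    return t, p, report
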