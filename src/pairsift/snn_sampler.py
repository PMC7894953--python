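"""Stage 1: shared-nearest-neighbour pooling and k-medoids representatives.

Plain nearest-neighbour distances degrade in high-dimensional descriptor
space, so candidate negatives are gathered through *shared* nearest
neighbours: SNN_k(x, y) = |NN_k(x) ∩ NN_k(y)|.  For every approved
interaction (d, t) the shared-neighbour pool of the drug and of the target
is clustered with k-medoids (the cluster count chosen by the
Calinski-Harabasz criterion) and the cartesian product of the medoid
representatives, minus approved pairs, becomes the label-0 candidate set.
This shrinks the unannotated pair space by orders of magnitude while
keeping pairs that live near known interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import calinski_harabasz_score

from .data_model import FeatureMatrix, InteractionSet

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborLists",
    "NegativeCandidateSet",
    "knn_indices",
    "snn_count",
    "snn_pool",
    "cluster_representatives",
    "build_negative_candidates",
]

DEFAULT_K = 11  # neighbourhood size balancing pool size against dimension


@dataclass
class NeighborLists:
    """Per entity, the indices of its k nearest others (self excluded)."""

    indices: np.ndarray  # (n, k), ranked by ascending L2 distance
    k: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 2 or self.indices.shape[1] != self.k:
            raise ValueError("indices must be (n_entities, k)")
        owners = np.arange(self.indices.shape[0])[:, None]
        if np.any(self.indices == owners):
            raise ValueError("an entity may not be its own neighbour")

    @property
    def n(self) -> int:
        return self.indices.shape[0]


@dataclass
class NegativeCandidateSet:
    """Label-0 candidate pairs with the positive pair that seeded each."""

    pairs: list[tuple[str, str]]
    provenance: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def validate_disjoint(self, inter: InteractionSet) -> None:
        overlap = set(self.pairs) & inter.positive_pairs
        if overlap:
            raise AssertionError(f"candidates overlap positives: {sorted(overlap)[:5]}")


def _as_array(fm: FeatureMatrix | np.ndarray) -> np.ndarray:
    return fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=float)


def knn_indices(fm: FeatureMatrix | np.ndarray, k: int) -> NeighborLists:
    """Exact k-nearest-neighbour lists under L2, ties broken by ascending index."""
    X = _as_array(fm)
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < n_entities={n}")
    dist = cdist(X, X)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")  # stable => ties by index
    return NeighborLists(order[:, :k], k)


def snn_count(nl: NeighborLists, i: int, j: int) -> int:
    """|NN_k(i) ∩ NN_k(j)|; symmetric, bounded by k."""
    if i == j:
        logger.warning("snn_count called with i == j == %d; full overlap k=%d", i, nl.k)
        return nl.k
    return int(np.intersect1d(nl.indices[i], nl.indices[j]).size)


def snn_pool(
    fm: FeatureMatrix | np.ndarray,
    seed_index: int,
    k: int,
    neighbors: NeighborLists | None = None,
) -> set[int]:
    """Union of shared-neighbour *objects* of the seed with every other entity.

    Returns every member of NN_k(seed) that also appears in at least one
    other entity's neighbour list, i.e. the union over r != seed of
    NN_k(seed) ∩ NN_k(r).  The seed itself is never in the pool.
    """
    nl = neighbors if neighbors is not None else knn_indices(fm, k)
    # membership count per object over all lists; the seed's own list
    # contributes one, so >= 2 means some other list shares the object
    counts = np.bincount(nl.indices.ravel(), minlength=nl.n)
    pool = {int(x) for x in nl.indices[seed_index] if counts[x] >= 2}
    pool.discard(int(seed_index))
    return pool


def _pam(dist: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """PAM-style k-medoids on a precomputed distance matrix.

    Greedy BUILD initialisation followed by alternate assignment / medoid
    update.  Fully deterministic: all ties resolve to the lowest index.
    Returns cluster labels (medoid rank per point).
    """
    n = dist.shape[0]
    medoids = [int(dist.sum(axis=0).argmin())]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        best_cost, best_c = np.inf, -1
        for c in range(n):
            if c in medoids:
                continue
            cost = np.minimum(current, dist[:, c]).sum()
            if cost < best_cost - 1e-12:
                best_cost, best_c = cost, c
        medoids.append(best_c)
    medoids = sorted(medoids)
    for _ in range(max_iter):
        labels = dist[:, medoids].argmin(axis=1)
        new_medoids = []
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:  # keep the old medoid for an empty cluster
                new_medoids.append(medoids[c])
                continue
            within = dist[np.ix_(members, members)].sum(axis=0)
            new_medoids.append(int(members[within.argmin()]))
        new_medoids = sorted(new_medoids)
        if new_medoids == medoids:
            break
        medoids = new_medoids
    labels = dist[:, medoids].argmin(axis=1)
    return np.asarray(medoids, dtype=int), labels


MIN_STRUCTURE_SCORE = 5.0  # pseudo-F evidence required before splitting a pool


def cluster_representatives(
    points: np.ndarray,
    k_max: int = 10,
    seed: int = 0,
    min_structure: float = MIN_STRUCTURE_SCORE,
) -> np.ndarray:
    """Medoid representatives of a point set, count picked by Calinski-Harabasz.

    k-medoids is run for every candidate cluster count and the partition
    maximising the Calinski-Harabasz index is kept; its medoids (actual
    rows of ``points``) are returned as row indices.  Degenerate sizes pass
    through: 0 points -> empty, 1 -> itself, 2 -> both.

    Two guards keep the CH selection meaningful on small pools.  The index
    is a pseudo-F statistic, so (a) candidate counts are limited to
    k <= n/2 — beyond that the within-cluster dispersion rests on fewer
    degrees of freedom than there are clusters and the index spikes on
    singleton clusters — and (b) a partition is only accepted when its CH
    value shows decisive structure (``min_structure``, default 5; the
    statistic hovers near 1 on a structureless unimodal pool for every
    count).  When no candidate count qualifies — including coincident
    points, where the index is undefined — the pool is treated as one
    cluster and its single overall medoid returned.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n == 0:
        return np.empty(0, dtype=int)
    if n == 1:
        return np.array([0])
    if n == 2:
        return np.array([0, 1])
    dist = cdist(points, points)
    best_score, best_medoids = -np.inf, None
    for k in range(2, min(k_max, n // 2) + 1):
        medoids, labels = _pam(dist, k)
        if np.unique(labels).size < 2:
            continue
        try:
            with np.errstate(divide="ignore", invalid="ignore"):
                score = calinski_harabasz_score(points, labels)
        except ValueError:
            continue
        if not np.isfinite(score):
            continue
        if score > best_score:
            best_score, best_medoids = score, medoids
    if best_medoids is None or best_score < min_structure:
        return np.array([int(dist.sum(axis=0).argmin())])
    return best_medoids


def build_negative_candidates(
    inter: InteractionSet,
    drugs: FeatureMatrix,
    targets: FeatureMatrix,
    k: int = DEFAULT_K,
    k_max_clusters: int = 10,
    seed: int = 0,
) -> NegativeCandidateSet:
    """Candidate negatives from medoid representatives of SNN pools.

    For each approved pair (d, t): the shared-neighbour pool of d over the
    drug matrix and of t over the target matrix are clustered and their
    medoid entities combined by cartesian product; any combination that is
    itself approved is dropped.  Candidates are recorded by entity id with
    the seeding positive pair as provenance (first seeder wins), and the
    result is deterministic for identical inputs.
    """
    nl_d = knn_indices(drugs, k)
    nl_t = knn_indices(targets, k)

    def make_rep_lookup(fm: FeatureMatrix, nl: NeighborLists):
        cache: dict[int, list[int]] = {}

        def reps(idx: int) -> list[int]:
            if idx not in cache:
                pool = sorted(snn_pool(fm, idx, k, neighbors=nl))
                if not pool:
                    cache[idx] = []
                else:
                    med = cluster_representatives(
                        fm.values[pool], k_max=k_max_clusters, seed=seed
                    )
                    cache[idx] = [pool[m] for m in med]
            return cache[idx]

        return reps

    drug_reps = make_rep_lookup(drugs, nl_d)
    target_reps = make_rep_lookup(targets, nl_t)

    ordered_positives = sorted(
        inter.positive_list,
        key=lambda p: (drugs.index_of(p[0]), targets.index_of(p[1])),
    )
    candidates: dict[tuple[str, str], tuple[str, str]] = {}
    for d_id, t_id in ordered_positives:
        rd = drug_reps(drugs.index_of(d_id))
        rt = target_reps(targets.index_of(t_id))
        for di in rd:
            for ti in rt:
                pair = (drugs.entity_ids[di], targets.entity_ids[ti])
                if pair in inter.positive_pairs or pair in candidates:
                    continue
                candidates[pair] = (d_id, t_id)
    out = NegativeCandidateSet(list(candidates), candidates)
    out.validate_disjoint(inter)
    return out
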