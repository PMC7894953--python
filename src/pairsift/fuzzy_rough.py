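"""Fuzzy-rough approximation machinery for scoring candidate pairs.

Objects (drug-target pair vectors) are compared per feature with a fuzzy
similarity relation — linear/tolerance ``1 - |x - y| / range``, Gaussian
``exp(-(x - y)^2 / 2 sigma^2)`` or triangular ``max(0, 1 - |x - y| / sigma)``
— and the per-feature degrees are aggregated into a fuzzy indiscernibility
relation with a t-norm (Lukasiewicz by default, minimum as an option).

With a crisp decision attribute, the fuzzy-rough *upper* approximation of a
concept at x is ``sup_y T(R(x, y), mu_Y(y))``: the degree to which x
*possibly* belongs to the concept.  The *lower* approximation
``inf_y I(R(x, y), mu_Y(y))`` is the degree of certain membership.  Both use
the Lukasiewicz t-norm / implicator pair.

Candidate negatives are scored with the group-averaged upper approximation
(FRUA): positives are split into m groups and candidates into n groups,
every candidate's upper-approximation degree towards the positive concept
is computed once per positive group, and the m degrees are averaged.  The
grouping bounds the quadratic cost of the similarity relation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import DecisionTable, FeatureStats

logger = logging.getLogger(__name__)

__all__ = [
    "FuzzyRelationConfig",
    "FruaScores",
    "lukasiewicz_tnorm",
    "lukasiewicz_implicator",
    "feature_similarity",
    "pairwise_indiscernibility",
    "indiscernibility",
    "relation_matrix",
    "upper_approximation",
    "lower_approximation",
    "averaged_frua",
    "reset_similarity_eval_count",
    "similarity_eval_count",
]

SIMILARITY_VARIANTS = ("linear", "gaussian", "triangular")
AGGREGATIONS = ("lukasiewicz", "min")

# counter of elementary per-feature similarity evaluations, used to verify
# the O(n^2 * |C|) cost profile of relation construction
_similarity_evals = 0


def reset_similarity_eval_count() -> None:
    global _similarity_evals
    _similarity_evals = 0


def similarity_eval_count() -> int:
    return _similarity_evals


def _bump(n: int) -> None:
    global _similarity_evals
    _similarity_evals += int(n)


@dataclass
class FuzzyRelationConfig:
    """Choice of per-feature similarity and of the aggregation t-norm."""

    similarity: str = "linear"
    aggregation: str = "lukasiewicz"

    def __post_init__(self) -> None:
        if self.similarity not in SIMILARITY_VARIANTS:
            raise ValueError(f"unknown similarity variant {self.similarity!r}")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"unknown aggregation t-norm {self.aggregation!r}")


@dataclass
class FruaScores:
    """Group-averaged upper-approximation degree per candidate."""

    scores: np.ndarray
    m: int
    n: int
    positive_groups: list[np.ndarray] = field(default_factory=list)
    candidate_groups: list[np.ndarray] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("FRUA scores must lie in [0, 1]")


def _check_unit(name: str, *values) -> None:
    for v in values:
        arr = np.asarray(v, dtype=float)
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError(f"{name}: degrees must lie in [0, 1]")


def lukasiewicz_tnorm(a, b):
    """T(a, b) = max(0, a + b - 1)."""
    _check_unit("lukasiewicz_tnorm", a, b)
    out = np.maximum(0.0, np.asarray(a, dtype=float) + np.asarray(b, dtype=float) - 1.0)
    return float(out) if out.ndim == 0 else out


def lukasiewicz_implicator(a, b):
    """I(a, b) = min(1, 1 - a + b)."""
    _check_unit("lukasiewicz_implicator", a, b)
    out = np.minimum(1.0, 1.0 - np.asarray(a, dtype=float) + np.asarray(b, dtype=float))
    return float(out) if out.ndim == 0 else out


def feature_similarity(
    a: float,
    b: float,
    stats: FeatureStats,
    variant: str = "linear",
    feature: int = 0,
) -> float:
    """Similarity degree of two values on one feature, in [0, 1].

    A degenerate feature (zero range for the linear variant, zero variance
    for the Gaussian/triangular ones) cannot distinguish any two objects and
    yields degree 1.
    """
    _bump(1)
    diff = abs(float(a) - float(b))
    if variant == "linear":
        rng = float(stats.range[feature])
        if rng <= 0:
            logger.debug("zero range on feature %d; similarity defined as 1", feature)
            return 1.0
        return float(np.clip(1.0 - diff / rng, 0.0, 1.0))
    if variant == "gaussian":
        var = float(stats.variance[feature])
        if var <= 0:
            logger.debug("zero variance on feature %d; similarity defined as 1", feature)
            return 1.0
        return float(math.exp(-(diff**2) / (2.0 * var)))
    if variant == "triangular":
        sigma = float(stats.std[feature])
        if sigma <= 0:
            logger.debug("zero variance on feature %d; similarity defined as 1", feature)
            return 1.0
        return float(max(0.0, 1.0 - diff / sigma))
    raise ValueError(f"unknown similarity variant {variant!r}")


def _feature_similarity_block(
    x: np.ndarray, y: np.ndarray, stats: FeatureStats, variant: str, f: int
) -> np.ndarray:
    """Similarity of every x against every y on feature f; shape (|x|, |y|)."""
    diff = np.abs(x[:, None] - y[None, :])
    if variant == "linear":
        rng = float(stats.range[f])
        if rng <= 0:
            return np.ones_like(diff)
        return np.clip(1.0 - diff / rng, 0.0, 1.0)
    if variant == "gaussian":
        var = float(stats.variance[f])
        if var <= 0:
            return np.ones_like(diff)
        return np.exp(-(diff**2) / (2.0 * var))
    if variant == "triangular":
        sigma = float(stats.std[f])
        if sigma <= 0:
            return np.ones_like(diff)
        return np.maximum(0.0, 1.0 - diff / sigma)
    raise ValueError(f"unknown similarity variant {variant!r}")


def pairwise_indiscernibility(
    X: np.ndarray,
    Y: np.ndarray,
    stats: FeatureStats,
    cfg: FuzzyRelationConfig | None = None,
) -> np.ndarray:
    """Fuzzy indiscernibility R(x, y) for every row of X against every row of Y.

    Per-feature degrees are folded with the configured t-norm.  The n-ary
    Lukasiewicz t-norm telescopes to ``max(0, sum_f R_f - (|C| - 1))``, so
    the relation is accumulated feature by feature without materialising the
    (|X|, |Y|, |C|) tensor.
    """
    cfg = cfg or FuzzyRelationConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must share the attribute space")
    d = X.shape[1]
    if d == 0:
        raise ValueError("empty attribute set")
    if cfg.aggregation == "lukasiewicz":
        acc = np.zeros((X.shape[0], Y.shape[0]))
        for f in range(d):
            acc += 1.0 - _feature_similarity_block(X[:, f], Y[:, f], stats, cfg.similarity, f)
        rel = np.clip(1.0 - acc, 0.0, 1.0)
    else:  # min
        rel = np.ones((X.shape[0], Y.shape[0]))
        for f in range(d):
            np.minimum(
                rel,
                _feature_similarity_block(X[:, f], Y[:, f], stats, cfg.similarity, f),
                out=rel,
            )
        rel = np.clip(rel, 0.0, 1.0)
    _bump(X.shape[0] * Y.shape[0] * d)
    return rel


def indiscernibility(
    x: np.ndarray,
    y: np.ndarray,
    P: Sequence[int],
    stats: FeatureStats,
    cfg: FuzzyRelationConfig | None = None,
) -> float:
    """R_P(x, y): indiscernibility of two objects on the attribute subset P."""
    P = np.asarray(P, dtype=int)
    if P.size == 0:
        raise ValueError("attribute subset P must be nonempty")
    x = np.asarray(x, dtype=float).ravel()[P]
    y = np.asarray(y, dtype=float).ravel()[P]
    rel = pairwise_indiscernibility(x[None, :], y[None, :], stats.subset(P), cfg)
    return float(rel[0, 0])


def relation_matrix(
    table: DecisionTable,
    stats: FeatureStats,
    cfg: FuzzyRelationConfig | None = None,
) -> np.ndarray:
    """Full n-by-n indiscernibility relation of a decision table."""
    return pairwise_indiscernibility(table.X, table.X, stats, cfg)


def upper_approximation(
    x: np.ndarray,
    table: DecisionTable,
    concept: int,
    stats: FeatureStats,
    cfg: FuzzyRelationConfig | None = None,
) -> float:
    """sup_y T(R(x, y), mu_Y(y)) with crisp concept membership.

    With mu_Y in {0, 1} and any t-norm, non-members contribute T(., 0) = 0,
    so the supremum reduces to the maximum indiscernibility over concept
    members (exactly the literal form, computed cheaper).
    """
    members = table.class_mask(concept)
    if not members.any():
        logger.warning("no member of concept %r in table; upper approximation 0", concept)
        return 0.0
    x = np.asarray(x, dtype=float).ravel()
    rel = pairwise_indiscernibility(x[None, :], table.X[members], stats, cfg)
    return float(np.clip(rel.max(), 0.0, 1.0))


def lower_approximation(
    x: np.ndarray,
    table: DecisionTable,
    concept: int,
    stats: FeatureStats,
    cfg: FuzzyRelationConfig | None = None,
) -> float:
    """inf_y I(R(x, y), mu_Y(y)) with crisp concept membership."""
    x = np.asarray(x, dtype=float).ravel()
    rel = pairwise_indiscernibility(x[None, :], table.X, stats, cfg)[0]
    mu = table.class_mask(concept).astype(float)
    degrees = np.minimum(1.0, 1.0 - rel + mu)
    return float(np.clip(degrees.min(), 0.0, 1.0))


def averaged_frua(
    X_pos: np.ndarray,
    X_cand: np.ndarray,
    m: int,
    n: int,
    stats: FeatureStats,
    cfg: FuzzyRelationConfig | None = None,
    seed: int = 0,
) -> FruaScores:
    """Group-averaged fuzzy-rough upper approximation of every candidate.

    Positives are shuffled (seeded) and split into m contiguous groups,
    candidates likewise into n groups.  For every (positive-group,
    candidate-group) pairing a decision table of that positive group
    (label 1) plus that candidate group (label 0) is formed and each
    candidate's upper approximation of the positive concept computed; the
    final score is the mean of a candidate's m per-table degrees.

    With m = n = 1 this is exactly the single-table upper approximation
    against the full positive set.
    """
    X_pos = np.atleast_2d(np.asarray(X_pos, dtype=float))
    X_cand = np.atleast_2d(np.asarray(X_cand, dtype=float))
    p, q = X_pos.shape[0], X_cand.shape[0]
    if p == 0:
        raise ValueError("empty positive set")
    if q == 0:
        raise ValueError("empty candidate set")
    if not 1 <= m <= p:
        raise ValueError(f"m={m} must be in [1, n_positives={p}]")
    if not 1 <= n <= q:
        raise ValueError(f"n={n} must be in [1, n_candidates={q}]")
    rng = np.random.default_rng(seed)
    pos_groups = [np.sort(g) for g in np.array_split(rng.permutation(p), m)]
    cand_groups = [np.sort(g) for g in np.array_split(rng.permutation(q), n)]
    total = np.zeros(q)
    for pg in pos_groups:
        for cg in cand_groups:
            rel = pairwise_indiscernibility(X_cand[cg], X_pos[pg], stats, cfg)
            total[cg] += rel.max(axis=1)
    scores = np.clip(total / m, 0.0, 1.0)
    return FruaScores(scores, m, n, pos_groups, cand_groups, seed)
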