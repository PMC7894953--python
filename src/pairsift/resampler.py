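"""Threshold-based under-sampling on FRUA scores and ADASYN balancing.

Two cut-offs act on the candidate scores: candidates scoring at or above
the promotion threshold t_p (near 1) are relabelled positive — they are
indistinguishable from known interactions under the fuzzy-rough relation —
while candidates at or below the selection threshold t_q (near 0) are kept
as the negative class Z.  Everything strictly between is discarded as
ambiguous.  When the surviving classes are still imbalanced beyond
tolerance, the minority class is augmented with ADASYN: synthetic samples
interpolated between minority points and their minority neighbours,
generated preferentially where the minority is hardest to learn (most
majority-surrounded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingThresholds",
    "TrainingSet",
    "threshold_sample",
    "adasyn_balance",
    "assemble_training_set",
]

TAG_APPROVED = "approved"
TAG_PROMOTED = "promoted"
TAG_SELECTED = "selected_negative"
TAG_SYNTHETIC = "synthetic_adasyn"

BALANCE_TOLERANCE = 0.1  # |minority/majority - 1| <= 0.1 counts as balanced


@dataclass
class SamplingThresholds:
    """Promotion threshold t_p (near 1) and selection threshold t_q (near 0)."""

    t_p: float
    t_q: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_q < self.t_p <= 1.0):
            raise ValueError(
                f"thresholds must satisfy 0 <= t_q < t_p <= 1, got t_q={self.t_q}, t_p={self.t_p}"
            )


@dataclass
class TrainingSet:
    """Labelled pair samples with per-row provenance tags."""

    X: np.ndarray
    y: np.ndarray
    ids: list
    provenance: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=int)
        self.provenance = np.asarray(self.provenance, dtype=object)
        n = self.X.shape[0]
        if not (self.y.shape[0] == len(self.ids) == self.provenance.shape[0] == n):
            raise ValueError("X, y, ids and provenance must agree on sample count")

    @property
    def n_positive(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.y == 0).sum())

    @property
    def class_ratio(self) -> float:
        """minority / majority count ratio (1.0 = perfectly balanced)."""
        a, b = self.n_positive, self.n_negative
        if max(a, b) == 0:
            return 1.0
        return min(a, b) / max(a, b)


def threshold_sample(
    scores: np.ndarray, th: SamplingThresholds
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition candidate indices by score.

    Returns ``(promoted, selected_negative, discarded)`` index arrays:
    score >= t_p is promoted to the positive class, score <= t_q is kept
    as a negative, anything strictly between is discarded.  Both
    comparisons are inclusive.
    """
    s = np.asarray(getattr(scores, "scores", scores), dtype=float)
    promoted = s >= th.t_p
    negative = s <= th.t_q
    discarded = ~(promoted | negative)
    return (
        np.flatnonzero(promoted),
        np.flatnonzero(negative),
        np.flatnonzero(discarded),
    )


def adasyn_balance(
    ts: TrainingSet,
    seed: int = 0,
    k: int = 5,
    tolerance: float = BALANCE_TOLERANCE,
) -> TrainingSet:
    """Balance classes by adaptive synthetic oversampling of the minority.

    Already-balanced input (minority/majority >= 1 - tolerance) is returned
    unchanged.  Otherwise, for each minority point the fraction of majority
    samples among its k nearest neighbours (over all samples) weights how
    many synthetic points to interpolate between it and its minority
    neighbours, so generation concentrates where the minority is hardest to
    learn.  A minority class too small for neighbourhood estimation
    (< k + 1 points) falls back to random duplication.  Original samples
    are always preserved; synthetic rows are tagged.
    """
    n_pos, n_neg = ts.n_positive, ts.n_negative
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be nonempty")
    if ts.class_ratio >= 1.0 - tolerance:
        return ts
    rng = np.random.default_rng(seed)
    minority_label = 1 if n_pos < n_neg else 0
    min_idx = np.flatnonzero(ts.y == minority_label)
    X_min = ts.X[min_idx]
    G = max(n_pos, n_neg) - min(n_pos, n_neg)

    if min_idx.size < k + 1:
        logger.warning(
            "minority class of size %d < k+1=%d; falling back to random duplication",
            min_idx.size,
            k + 1,
        )
        pick = rng.integers(0, min_idx.size, size=G)
        synth = X_min[pick]
    else:
        # hardness r_i: fraction of majority points among the k nearest
        # neighbours of each minority point in the full sample
        nn_all = NearestNeighbors(n_neighbors=k + 1).fit(ts.X)
        _, neigh = nn_all.kneighbors(X_min)
        r = np.empty(min_idx.size)
        for i, (row, self_pos) in enumerate(zip(neigh, min_idx)):
            others = [j for j in row if j != self_pos][:k]
            r[i] = np.mean(ts.y[others] != minority_label)
        weights = np.full(r.size, 1.0 / r.size) if r.sum() == 0 else r / r.sum()
        # largest-remainder apportionment so exactly G synthetics are made
        raw = weights * G
        g = np.floor(raw).astype(int)
        short = G - g.sum()
        if short > 0:
            order = np.argsort(-(raw - g), kind="stable")
            g[order[:short]] += 1
        k_min = min(k, min_idx.size - 1)
        nn_min = NearestNeighbors(n_neighbors=k_min + 1).fit(X_min)
        _, neigh_min = nn_min.kneighbors(X_min)
        rows = []
        for i, gi in enumerate(g):
            if gi == 0:
                continue
            nbrs = [j for j in neigh_min[i] if j != i][:k_min]
            picks = rng.choice(nbrs, size=gi)
            lam = rng.random(gi)[:, None]
            rows.append(X_min[i][None, :] + lam * (X_min[picks] - X_min[i][None, :]))
        synth = np.vstack(rows) if rows else np.empty((0, ts.X.shape[1]))

    n_new = synth.shape[0]
    X = np.vstack([ts.X, synth])
    y = np.concatenate([ts.y, np.full(n_new, minority_label, dtype=int)])
    ids = list(ts.ids) + [("synthetic", i) for i in range(n_new)]
    prov = np.concatenate([ts.provenance, np.full(n_new, TAG_SYNTHETIC, dtype=object)])
    return TrainingSet(X, y, ids, prov)


def _as_block(block, width: int | None):
    """Normalize an (X, ids) tuple; None or empty -> (0, width) block."""
    if block is None:
        X = np.empty((0, width or 0))
        return X, []
    X, ids = block
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        X = X.reshape(0, width or (X.shape[1] if X.ndim == 2 else 0))
    X = np.atleast_2d(X)
    ids = list(ids)
    if X.shape[0] != len(ids):
        raise ValueError("block X and ids disagree on sample count")
    return X, ids


def assemble_training_set(
    approved,
    promoted,
    selected_negatives,
    balance: bool = True,
    seed: int = 0,
    tolerance: float = BALANCE_TOLERANCE,
) -> TrainingSet:
    """Combine approved + promoted positives with selected negatives.

    Each block is an ``(X, ids)`` tuple (``promoted`` may be None/empty).
    ADASYN runs only when ``balance`` is true and the class imbalance
    exceeds tolerance; when threshold selection alone balanced the classes
    no synthetic rows are added.  Provenance of every row is preserved.
    """
    Xa, ida = _as_block(approved, None)
    width = Xa.shape[1]
    Xp, idp = _as_block(promoted, width)
    Xn, idn = _as_block(selected_negatives, width)
    if Xa.shape[0] + Xp.shape[0] == 0:
        raise ValueError("no positive class")
    if Xn.shape[0] == 0:
        raise ValueError("no negative class")
    X = np.vstack([Xa, Xp, Xn])
    y = np.concatenate(
        [np.ones(Xa.shape[0] + Xp.shape[0], dtype=int), np.zeros(Xn.shape[0], dtype=int)]
    )
    ids = ida + idp + idn
    prov = np.concatenate(
        [
            np.full(Xa.shape[0], TAG_APPROVED, dtype=object),
            np.full(Xp.shape[0], TAG_PROMOTED, dtype=object),
            np.full(Xn.shape[0], TAG_SELECTED, dtype=object),
        ]
    )
    ts = TrainingSet(X, y, ids, prov)
    if balance and ts.class_ratio < 1.0 - tolerance:
        ts = adasyn_balance(ts, seed=seed, tolerance=tolerance)
    return ts
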