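"""Containers, I/O and preprocessing for drug/target feature data.

A drug or a protein target is represented by a row of numeric descriptors
(a :class:`FeatureMatrix`).  Approved interactions are held in an
:class:`InteractionSet`; every (drug, target) pair not on the approved list
is an *unannotated* pair, the universe from which negative training samples
are later drawn.  A classifier sample is the concatenation of a drug row
and a target row (:class:`PairSample`).

Descriptors are brought onto a common scale with per-feature min-max
normalization, and optionally compressed with incremental PCA before the
quadratic-cost fuzzy-similarity stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import IncrementalPCA

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "FeatureStats",
    "InteractionSet",
    "PairSample",
    "DecisionTable",
    "load_feature_matrix",
    "load_interactions",
    "minmax_normalize",
    "concat_pair",
    "fit_incremental_pca",
    "reduce_dimensions",
]


@dataclass
class FeatureStats:
    """Per-feature minimum, maximum and variance of a feature matrix.

    These are the quantities the fuzzy similarity relations need: the
    feature range for the linear (tolerance) relation and the variance /
    standard deviation for the Gaussian and triangular relations.
    """

    minimum: np.ndarray
    maximum: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if not (self.minimum.shape == self.maximum.shape == self.variance.shape):
            raise ValueError("minimum, maximum and variance must share a shape")
        if np.any(self.variance < 0):
            raise ValueError("variance must be non-negative")
        if np.any(self.maximum < self.minimum):
            raise ValueError("maximum must be >= minimum")

    @property
    def range(self) -> np.ndarray:
        return self.maximum - self.minimum

    @property
    def std(self) -> np.ndarray:
        return np.sqrt(self.variance)

    @property
    def n_features(self) -> int:
        return self.minimum.size

    def subset(self, features: Sequence[int]) -> "FeatureStats":
        idx = np.asarray(features, dtype=int)
        return FeatureStats(self.minimum[idx], self.maximum[idx], self.variance[idx])

    @classmethod
    def from_matrix(cls, values: "np.ndarray | FeatureMatrix") -> "FeatureStats":
        if isinstance(values, FeatureMatrix):
            values = values.values
        values = np.asarray(values, dtype=float)
        return cls(values.min(axis=0), values.max(axis=0), values.var(axis=0))


@dataclass
class FeatureMatrix:
    """Named entities (rows) by named numeric features (columns)."""

    entity_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.entity_ids = [str(e) for e in self.entity_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.entity_ids), len(self.feature_names)):
            raise ValueError(
                f"shape mismatch: {self.values.shape} vs "
                f"({len(self.entity_ids)}, {len(self.feature_names)})"
            )
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("duplicate entity ids")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains missing or non-finite values")
        self._index = {e: i for i, e in enumerate(self.entity_ids)}

    @property
    def n_entities(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def index_of(self, entity_id: str) -> int:
        return self._index[entity_id]

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self._index[entity_id]]


@dataclass
class InteractionSet:
    """Approved (drug, target) pairs over explicit drug/target universes.

    The positive class of the prediction task is ``positive_pairs``; the
    remaining ``n_drugs * n_targets - len(positive_pairs)`` combinations are
    the unannotated pairs from which negatives are sampled.
    """

    drug_ids: list[str]
    target_ids: list[str]
    positive_pairs: set[tuple[str, str]]
    positive_list: list[tuple[str, str]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.drug_ids = [str(d) for d in self.drug_ids]
        self.target_ids = [str(t) for t in self.target_ids]
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("duplicate drug ids")
        if len(set(self.target_ids)) != len(self.target_ids):
            raise ValueError("duplicate target ids")
        self.positive_pairs = {(str(d), str(t)) for d, t in self.positive_pairs}
        if not self.positive_pairs:
            raise ValueError("no positive interactions")
        drugs, targets = set(self.drug_ids), set(self.target_ids)
        for d, t in self.positive_pairs:
            if d not in drugs:
                raise ValueError(f"pair references unknown drug id {d!r}")
            if t not in targets:
                raise ValueError(f"pair references unknown target id {t!r}")
        if self.positive_list is None:
            self.positive_list = sorted(self.positive_pairs)
        else:
            self.positive_list = [(str(d), str(t)) for d, t in self.positive_list]

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_possible_pairs(self) -> int:
        return self.n_drugs * self.n_targets

    @property
    def n_unannotated(self) -> int:
        return self.n_possible_pairs - len(self.positive_pairs)


@dataclass
class PairSample:
    """A drug-target pair: concatenated feature vector plus a 0/1 label."""

    drug_id: str
    target_id: str
    vector: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class DecisionTable:
    """Samples as objects with conditional attributes and a crisp decision.

    ``X`` holds the conditional attribute values (one row per object),
    ``labels`` the crisp decision attribute.
    """

    X: np.ndarray
    labels: np.ndarray
    ids: list | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.ndim != 2 or self.labels.ndim != 1:
            raise ValueError("X must be 2-D and labels 1-D")
        if self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("X and labels disagree on sample count")

    @property
    def n_objects(self) -> int:
        return self.X.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.X.shape[1]

    def class_mask(self, concept: int) -> np.ndarray:
        return self.labels == concept

    @classmethod
    def from_samples(cls, samples: Sequence[PairSample]) -> "DecisionTable":
        X = np.vstack([s.vector for s in samples])
        labels = np.array([s.label for s in samples], dtype=int)
        ids = [(s.drug_id, s.target_id) for s in samples]
        return cls(X, labels, ids)


def load_feature_matrix(path: str | Path, delimiter: str | None = None) -> FeatureMatrix:
    """Read an entities-by-features table from delimited text.

    First column: entity id; header row: feature names; body: numeric.
    The delimiter is auto-detected when not given.  Missing or non-numeric
    cells are rejected with the offending row/column named.
    """
    import csv as _csv

    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            index_col=0,
            engine="python" if delimiter is None else "c",
        )
    except (pd.errors.EmptyDataError, _csv.Error) as exc:
        raise ValueError(f"{path}: no entities") from exc
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no entities")
    ids = [str(i) for i in df.index]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicated entity id(s): {dup}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            val = df.loc[row, col]
            if pd.isna(val):
                raise ValueError(f"{path}: missing value at row {row!r}, column {col!r}")
            raise ValueError(
                f"{path}: non-numeric value {val!r} at row {row!r}, column {col!r}"
            )
    values = df.apply(pd.to_numeric).to_numpy(dtype=float)
    return FeatureMatrix(ids, [str(c) for c in df.columns], values)


def load_interactions(
    path: str | Path,
    drugs: FeatureMatrix | None = None,
    targets: FeatureMatrix | None = None,
    delimiter: str | None = None,
) -> InteractionSet:
    """Read approved (drug_id, target_id) pairs from two-column text.

    Duplicate lines are dropped with a warning.  When feature matrices are
    supplied, their entity orders define the drug/target universes and every
    pair must reference a known entity; otherwise the universes are the ids
    seen in the file, in order of first appearance.
    """
    import csv as _csv

    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            header=None,
            names=["drug_id", "target_id"],
            dtype=str,
            engine="python" if delimiter is None else "c",
        )
    except (pd.errors.EmptyDataError, _csv.Error) as exc:
        raise ValueError(f"{path}: no positive interactions") from exc
    # tolerate an optional literal header line
    if len(df) and list(df.iloc[0]) == ["drug_id", "target_id"]:
        df = df.iloc[1:]
    if df.empty:
        raise ValueError(f"{path}: no positive interactions")
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for d, t in df.itertuples(index=False):
        p = (str(d), str(t))
        if p in seen:
            n_dup += 1
            continue
        seen.add(p)
        pairs.append(p)
    if n_dup:
        logger.warning("%s: dropped %d duplicate interaction line(s)", path, n_dup)
    if drugs is not None:
        drug_ids = list(drugs.entity_ids)
    else:
        drug_ids = list(dict.fromkeys(d for d, _ in pairs))
    if targets is not None:
        target_ids = list(targets.entity_ids)
    else:
        target_ids = list(dict.fromkeys(t for _, t in pairs))
    return InteractionSet(drug_ids, target_ids, seen, positive_list=pairs)


def minmax_normalize(fm: FeatureMatrix) -> tuple[FeatureMatrix, FeatureStats]:
    """Rescale every feature to [0, 1] by (v - min) / (max - min).

    A constant feature carries no information and is mapped to 0.  The
    returned stats describe the *normalized* matrix, ready for the fuzzy
    similarity relations downstream.
    """
    v = fm.values
    lo = v.min(axis=0)
    span = v.max(axis=0) - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span > 0, (v - lo) / np.where(span > 0, span, 1.0), 0.0)
    normalized = FeatureMatrix(list(fm.entity_ids), list(fm.feature_names), out)
    return normalized, FeatureStats.from_matrix(out)


def concat_pair(
    drug_row: np.ndarray,
    target_row: np.ndarray,
    label: int,
    drug_id: str = "",
    target_id: str = "",
    allow_empty: bool = False,
) -> PairSample:
    """Concatenate a drug vector and a target vector, drug features first."""
    drug_row = np.asarray(drug_row, dtype=float).ravel()
    target_row = np.asarray(target_row, dtype=float).ravel()
    if not allow_empty and (drug_row.size == 0 or target_row.size == 0):
        raise ValueError("empty drug or target vector")
    return PairSample(drug_id, target_id, np.concatenate([drug_row, target_row]), label)


def fit_incremental_pca(
    X: np.ndarray, n_components: int, batch_size: int | None = None
) -> IncrementalPCA:
    """Fit an incremental (mini-batch) PCA on ``X`` and return the model."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if not 1 <= n_components <= min(n, d):
        raise ValueError(
            f"n_components={n_components} must be in [1, min(n_entities={n}, n_features={d})]"
        )
    if batch_size is None:
        batch_size = max(n_components, min(n, 5 * n_components))
    if batch_size < n_components:
        raise ValueError("batch_size must be >= n_components")
    model = IncrementalPCA(n_components=n_components, batch_size=batch_size)
    model.fit(X)
    return model


def reduce_dimensions(
    fm: FeatureMatrix, n_components: int, batch_size: int | None = None
) -> FeatureMatrix:
    """Project a feature matrix onto its top principal components.

    Uses mini-batch incremental PCA so that arbitrarily many entities can be
    processed without holding the full covariance workspace in memory.
    """
    model = fit_incremental_pca(fm.values, n_components, batch_size)
    Z = model.transform(fm.values)
    width = max(3, len(str(n_components)))
    names = [f"pc{i + 1:0{width}d}" for i in range(n_components)]
    return FeatureMatrix(list(fm.entity_ids), names, Z)
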