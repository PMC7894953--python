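"""Synthetic drug/target fixture generator with planted block structure.

Emulates the structure the two-stage sampler exploits: drugs and targets
fall into feature-space clusters, each drug cluster is "compatible" with
one target cluster, and approved interactions concentrate inside those
compatible blocks (similar drugs hit similar targets).  A small fraction
of approved pairs is placed off-block as annotation noise — it is these
noisy seeds that let the sampler reach candidate pairs outside the
compatible blocks, mirroring the promiscuity of real interaction data.

The generator returns the ground-truth cluster and block assignments so
tests can assert, e.g., that shared-neighbour pools stay inside clusters
or that in-block pairs receive higher fuzzy-rough scores than off-block
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import FeatureMatrix, InteractionSet

__all__ = ["SyntheticSpec", "generate"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-block fixture.

    Defaults give a desk-scale problem (60 x 40 entities) that runs the
    full pipeline in seconds: continuous descriptors in the unit hypercube,
    3 drug clusters sharing 2 target clusters, within-cluster spread 0.1,
    30% of in-block pairs approved, 5% annotation noise.
    """

    n_drugs: int = 60
    n_targets: int = 40
    drug_dim: int = 30
    target_dim: int = 40
    n_drug_clusters: int = 3
    n_target_clusters: int = 2
    cluster_spread: float = 0.1
    interaction_density: float = 0.3
    noise_interactions: float = 0.05
    binary_features: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_targets", "drug_dim", "target_dim",
                     "n_drug_clusters", "n_target_clusters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_drug_clusters > self.n_drugs:
            raise ValueError("more drug clusters than drugs")
        if self.n_target_clusters > self.n_targets:
            raise ValueError("more target clusters than targets")
        if self.cluster_spread < 0:
            raise ValueError("cluster_spread must be non-negative")
        if not 0.0 <= self.interaction_density <= 1.0:
            raise ValueError("interaction_density must be in [0, 1]")
        if not 0.0 <= self.noise_interactions <= 1.0:
            raise ValueError("noise_interactions must be in [0, 1]")


def _cluster_assignment(n: int, c: int) -> np.ndarray:
    """Contiguous, nearly equal cluster blocks: [0,0,...,1,1,...,c-1,...]."""
    return np.concatenate([np.full(len(part), i) for i, part in
                           enumerate(np.array_split(np.arange(n), c))])


def _entity_features(
    rng: np.random.Generator, n: int, dim: int, assign: np.ndarray,
    n_clusters: int, spread: float, binary: bool,
) -> np.ndarray:
    if binary:
        # per-cluster Bernoulli fingerprint profiles (on-bits at 0.9, off at 0.1)
        profiles = np.where(rng.random((n_clusters, dim)) < 0.5, 0.9, 0.1)
        return (rng.random((n, dim)) < profiles[assign]).astype(float)
    centers = rng.uniform(0.0, 1.0, size=(n_clusters, dim))
    return centers[assign] + rng.normal(0.0, spread, size=(n, dim))


def generate(
    spec: SyntheticSpec | None = None,
) -> tuple[FeatureMatrix, FeatureMatrix, InteractionSet, dict]:
    """Build (drugs, targets, interactions, truth) for a planted-block spec.

    ``truth`` maps each entity id to its cluster, lists the compatible
    (drug-cluster, target-cluster) blocks, and enumerates every in-block
    pair.  Raises if the spec admits no approved pair at all (a density of
    zero), exercising the empty-interaction error path downstream.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    drug_assign = _cluster_assignment(spec.n_drugs, spec.n_drug_clusters)
    target_assign = _cluster_assignment(spec.n_targets, spec.n_target_clusters)

    drug_ids = [f"D{i:03d}" for i in range(spec.n_drugs)]
    target_ids = [f"T{i:03d}" for i in range(spec.n_targets)]
    Xd = _entity_features(rng, spec.n_drugs, spec.drug_dim, drug_assign,
                          spec.n_drug_clusters, spec.cluster_spread, spec.binary_features)
    Xt = _entity_features(rng, spec.n_targets, spec.target_dim, target_assign,
                          spec.n_target_clusters, spec.cluster_spread, spec.binary_features)
    drugs = FeatureMatrix(drug_ids, [f"d{j}" for j in range(spec.drug_dim)], Xd)
    targets = FeatureMatrix(target_ids, [f"t{j}" for j in range(spec.target_dim)], Xt)

    blocks = [(dc, dc % spec.n_target_clusters) for dc in range(spec.n_drug_clusters)]
    block_of_drug_cluster = dict(blocks)

    block_pairs: list[tuple[str, str]] = []
    for di in range(spec.n_drugs):
        tc = block_of_drug_cluster[int(drug_assign[di])]
        for ti in range(spec.n_targets):
            if int(target_assign[ti]) == tc:
                block_pairs.append((drug_ids[di], target_ids[ti]))

    n_pos = int(round(spec.interaction_density * len(block_pairs)))
    pick = rng.choice(len(block_pairs), size=n_pos, replace=False) if n_pos else []
    positives = [block_pairs[i] for i in sorted(pick)]

    off_block = [
        (d, t)
        for d in drug_ids
        for t in target_ids
        if (d, t) not in set(block_pairs)
    ]
    n_noise = min(int(round(spec.noise_interactions * len(positives))), len(off_block))
    if n_noise:
        pick = rng.choice(len(off_block), size=n_noise, replace=False)
        positives.extend(off_block[i] for i in sorted(pick))

    inter = InteractionSet(drug_ids, target_ids, set(positives), positive_list=positives)
    truth = {
        "drug_clusters": {drug_ids[i]: int(drug_assign[i]) for i in range(spec.n_drugs)},
        "target_clusters": {target_ids[i]: int(target_assign[i]) for i in range(spec.n_targets)},
        "blocks": blocks,
        "block_pairs": set(block_pairs),
    }
    return drugs, targets, inter, truth
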