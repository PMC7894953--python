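"""End-to-end orchestration: normalize -> SNN sampling -> FRUA -> resample -> classify.

The stages compose as follows:

1. min-max normalize the drug and target descriptor matrices;
2. build candidate negatives from shared-nearest-neighbour pools and their
   k-medoids representatives;
3. assemble concatenated pair vectors for positives and candidates and
   (optionally) compress them with incremental PCA — the fuzzy similarity
   relation then operates on the reduced pair space;
4. score every candidate with the group-averaged fuzzy-rough upper
   approximation of the positive concept;
5. under-sample by threshold (promote near-1 candidates, keep near-0
   candidates as negatives) and ADASYN-balance if still needed;
6. train and evaluate a classifier under stratified CV or holdout.

When no selection threshold t_q is given, it is set adaptively to the
score quantile that keeps approximately as many negatives as there are
positives — the regime in which under-sampling alone balances the classes
and no oversampling is required.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .classify_eval import ClassifierSpec, EvalReport, evaluate
from .data_model import (
    FeatureMatrix,
    FeatureStats,
    InteractionSet,
    fit_incremental_pca,
    minmax_normalize,
)
from .fuzzy_rough import FruaScores, FuzzyRelationConfig, averaged_frua
from .resampler import SamplingThresholds, TrainingSet, assemble_training_set, threshold_sample
from .snn_sampler import NegativeCandidateSet, build_negative_candidates

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "pair_matrix"]


@dataclass
class PipelineConfig:
    """Tunable knobs of the full pipeline with desk-scale defaults.

    ``pca_components`` defaults to 10: the Lukasiewicz aggregation of
    per-feature similarities subtracts the summed per-feature dissimilarity,
    so over hundreds of raw features almost every relation degree clamps to
    zero; a compact principal-component pair space keeps the fuzzy relation
    informative while preserving the cluster geometry the scores rely on.
    """

    k: int = 11
    k_max_clusters: int = 10
    pca_enabled: bool = True
    pca_components: int = 10
    pca_batch_size: int | None = None
    similarity: str = "linear"
    aggregation: str = "lukasiewicz"
    group_size: int = 500
    t_p: float = 0.95
    t_q: float | None = None  # None -> adaptive quantile
    balance: bool = True
    classifier: ClassifierSpec = field(default_factory=lambda: ClassifierSpec("random_forest"))
    scheme: str = "cv5"
    seed: int = 0


@dataclass
class PipelineResult:
    candidates: NegativeCandidateSet
    scores: FruaScores
    thresholds: SamplingThresholds
    training_set: TrainingSet
    report: EvalReport
    counts: dict


def pair_matrix(
    drugs: FeatureMatrix, targets: FeatureMatrix, pairs: list[tuple[str, str]]
) -> np.ndarray:
    """Concatenated drug+target vectors (drug features first) for id pairs."""
    di = np.array([drugs.index_of(d) for d, _ in pairs], dtype=int)
    ti = np.array([targets.index_of(t) for _, t in pairs], dtype=int)
    return np.hstack([drugs.values[di], targets.values[ti]])


def _derived_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) % (2**31) for s in state]


def adaptive_selection_threshold(
    scores: np.ndarray, n_positives: int, t_p: float
) -> float:
    """Score quantile keeping ~n_positives negatives, strictly below t_p."""
    s = np.sort(np.asarray(scores, dtype=float))
    idx = min(n_positives, s.size) - 1
    t_q = float(s[max(idx, 0)])
    t_q = min(t_q, t_p - 1e-9)
    return max(t_q, 0.0)


def run_pipeline(
    drugs: FeatureMatrix,
    targets: FeatureMatrix,
    inter: InteractionSet,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every stage on one dataset and return all intermediate artifacts."""
    cfg = config or PipelineConfig()
    seeds = _derived_seeds(cfg.seed, 4)

    drugs_n, _ = minmax_normalize(drugs)
    targets_n, _ = minmax_normalize(targets)

    candidates = build_negative_candidates(
        inter, drugs_n, targets_n, k=cfg.k, k_max_clusters=cfg.k_max_clusters, seed=seeds[0]
    )
    if len(candidates) == 0:
        raise ValueError("sampler produced no candidate negatives")

    pos_pairs = list(inter.positive_list)
    X_pos = pair_matrix(drugs_n, targets_n, pos_pairs)
    X_cand = pair_matrix(drugs_n, targets_n, candidates.pairs)

    if cfg.pca_enabled:
        stacked = np.vstack([X_pos, X_cand])
        n_comp = min(cfg.pca_components, stacked.shape[0], stacked.shape[1])
        model = fit_incremental_pca(stacked, n_comp, cfg.pca_batch_size)
        X_pos = model.transform(X_pos)
        X_cand = model.transform(X_cand)

    stats = FeatureStats.from_matrix(np.vstack([X_pos, X_cand]))
    rel_cfg = FuzzyRelationConfig(cfg.similarity, cfg.aggregation)
    m = max(1, math.ceil(X_pos.shape[0] / cfg.group_size))
    n = max(1, math.ceil(X_cand.shape[0] / cfg.group_size))
    scores = averaged_frua(X_pos, X_cand, m, n, stats, rel_cfg, seed=seeds[1])

    t_q = (
        cfg.t_q
        if cfg.t_q is not None
        else adaptive_selection_threshold(scores.scores, len(pos_pairs), cfg.t_p)
    )
    th = SamplingThresholds(cfg.t_p, t_q)
    prom_idx, neg_idx, disc_idx = threshold_sample(scores.scores, th)

    ts = assemble_training_set(
        (X_pos, pos_pairs),
        (X_cand[prom_idx], [candidates.pairs[i] for i in prom_idx]),
        (X_cand[neg_idx], [candidates.pairs[i] for i in neg_idx]),
        balance=cfg.balance,
        seed=seeds[2],
    )
    report = evaluate(ts, cfg.classifier, scheme=cfg.scheme, seed=seeds[3])

    counts = {
        "n_drugs": inter.n_drugs,
        "n_targets": inter.n_targets,
        "n_positives": len(inter.positive_pairs),
        "n_unannotated": inter.n_unannotated,
        "n_candidates": len(candidates),
        "reduction_factor": inter.n_unannotated / len(candidates),
        "n_promoted": int(prom_idx.size),
        "n_selected_negatives": int(neg_idx.size),
        "n_discarded": int(disc_idx.size),
        "n_synthetic": int((ts.provenance == "synthetic_adasyn").sum()),
        "n_train_positive": ts.n_positive,
        "n_train_negative": ts.n_negative,
    }
    logger.info("pipeline counts: %s", counts)
    return PipelineResult(candidates, scores, th, ts, report, counts)
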