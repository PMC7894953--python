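"""Fuzzy similarity, Lukasiewicz operators, approximations, averaged FRUA.

Oracles here are deliberately literal: explicit Python double loops over
the sup/T and inf/I definitions, with per-feature similarities computed
one value pair at a time.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairsift import (
    DecisionTable,
    FeatureStats,
    FuzzyRelationConfig,
    averaged_frua,
    feature_similarity,
    indiscernibility,
    lower_approximation,
    lukasiewicz_implicator,
    lukasiewicz_tnorm,
    upper_approximation,
)

unit = st.floats(0.0, 1.0)


def unit_stats(d):
    """Stats of a notional [0,1] feature space with variance 1/12 (uniform)."""
    return FeatureStats(np.zeros(d), np.ones(d), np.full(d, 1.0 / 12.0))


# ---------------------------------------------------------------- oracles
def oracle_similarity(a, b, stats, variant, f):
    if variant == "linear":
        rng = stats.maximum[f] - stats.minimum[f]
        return 1.0 if rng <= 0 else max(0.0, min(1.0, 1 - abs(a - b) / rng))
    if variant == "gaussian":
        var = stats.variance[f]
        return 1.0 if var <= 0 else math.exp(-((a - b) ** 2) / (2 * var))
    sigma = math.sqrt(stats.variance[f])
    return 1.0 if sigma <= 0 else max(0.0, min(1.0, 1 - abs(a - b) / sigma))


def oracle_relation(x, y, stats, cfg):
    degs = [oracle_similarity(x[f], y[f], stats, cfg.similarity, f) for f in range(len(x))]
    if cfg.aggregation == "min":
        return min(degs)
    out = degs[0]
    for d in degs[1:]:
        out = max(0.0, out + d - 1.0)  # left-to-right Lukasiewicz fold
    return out


def oracle_upper(x, table, concept, stats, cfg):
    """Literal sup_y T(R(x,y), mu_Y(y)) over every table object."""
    best = 0.0
    for y_row, label in zip(table.X, table.labels):
        mu = 1.0 if label == concept else 0.0
        r = oracle_relation(x, y_row, stats, cfg)
        best = max(best, max(0.0, r + mu - 1.0))
    return best


def oracle_lower(x, table, concept, stats, cfg):
    worst = 1.0
    for y_row, label in zip(table.X, table.labels):
        mu = 1.0 if label == concept else 0.0
        r = oracle_relation(x, y_row, stats, cfg)
        worst = min(worst, min(1.0, 1.0 - r + mu))
    return worst


ALL_CFGS = [
    FuzzyRelationConfig(sim, agg)
    for sim in ("linear", "gaussian", "triangular")
    for agg in ("lukasiewicz", "min")
]


def random_table(rng, n=12, d=3):
    X = rng.random((n, d))
    labels = rng.integers(0, 2, size=n)
    labels[0], labels[1] = 0, 1  # both classes present
    return DecisionTable(X, labels)


# ----------------------------------------------------------------- tests
class TestOperators:
    @given(unit)
    def test_tnorm_boundary_law(self, b):
        assert lukasiewicz_tnorm(1.0, b) == pytest.approx(b)

    def test_pointwise_values(self):
        assert lukasiewicz_tnorm(0.7, 0.6) == pytest.approx(0.3)
        assert lukasiewicz_implicator(0.4, 0.9) == 1.0

    @pytest.mark.parametrize("a,b", [(-0.1, 0.5), (0.5, 1.1)])
    def test_out_of_range_rejected(self, a, b):
        with pytest.raises(ValueError):
            lukasiewicz_tnorm(a, b)
        with pytest.raises(ValueError):
            lukasiewicz_implicator(a, b)


class TestFeatureSimilarity:
    def test_linear_examples(self):
        s = unit_stats(1)
        assert feature_similarity(0.4, 0.4, s, "linear") == 1.0
        assert feature_similarity(0.0, 1.0, s, "linear") == 0.0

    def test_gaussian_at_one_sigma(self):
        s = FeatureStats([0.0], [1.0], [0.04])  # sigma = 0.2
        assert feature_similarity(0.5, 0.7, s, "gaussian") == pytest.approx(math.exp(-0.5))

    def test_degenerate_feature_gives_one(self):
        s = FeatureStats([0.3], [0.3], [0.0])
        for variant in ("linear", "gaussian", "triangular"):
            assert feature_similarity(0.1, 0.9, s, variant) == 1.0

    @pytest.mark.parametrize("variant", ["linear", "gaussian", "triangular"])
    @given(a=unit, b=unit)
    @settings(max_examples=40, deadline=None)
    def test_symmetric_unit_bounded_reflexive(self, variant, a, b):
        s = unit_stats(1)
        d1 = feature_similarity(a, b, s, variant)
        assert d1 == feature_similarity(b, a, s, variant)
        assert 0.0 <= d1 <= 1.0
        assert feature_similarity(a, a, s, variant) == 1.0


class TestIndiscernibility:
    def test_aggregation_examples(self):
        # two features with degrees 0.9 and 0.8
        s = unit_stats(2)
        x, y = np.array([0.0, 0.0]), np.array([0.1, 0.2])
        luk = indiscernibility(x, y, [0, 1], s, FuzzyRelationConfig("linear", "lukasiewicz"))
        mn = indiscernibility(x, y, [0, 1], s, FuzzyRelationConfig("linear", "min"))
        assert luk == pytest.approx(0.7)
        assert mn == pytest.approx(0.8)

    def test_reflexive(self, rng):
        x = rng.random(4)
        for cfg in ALL_CFGS:
            assert indiscernibility(x, x, [0, 1, 2, 3], unit_stats(4), cfg) == 1.0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            indiscernibility(np.zeros(2), np.ones(2), [], unit_stats(2))

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_monotone_nonincreasing_in_attribute_count(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.random(5), rng.random(5)
        s = unit_stats(5)
        for agg in ("lukasiewicz", "min"):
            cfg = FuzzyRelationConfig("linear", agg)
            prev = 1.0
            for size in range(1, 6):
                cur = indiscernibility(x, y, list(range(size)), s, cfg)
                assert cur <= prev + 1e-12
                prev = cur


class TestApproximations:
    def test_member_in_table_gives_upper_one(self, rng):
        table = random_table(rng)
        x = table.X[1]  # label 1
        assert upper_approximation(x, table, 1, unit_stats(3)) == 1.0

    def test_no_concept_member_gives_zero(self, rng, caplog):
        X = rng.random((5, 3))
        table = DecisionTable(X, np.zeros(5, dtype=int))
        with caplog.at_level("WARNING"):
            assert upper_approximation(X[0], table, 1, unit_stats(3)) == 0.0

    def test_all_members_give_lower_one(self, rng):
        X = rng.random((5, 3))
        table = DecisionTable(X, np.ones(5, dtype=int))
        assert lower_approximation(X[0], table, 1, unit_stats(3)) == 1.0

    def test_identical_nonmember_gives_lower_zero(self, rng):
        X = rng.random((4, 3))
        X[2] = X[0]
        labels = np.array([1, 1, 0, 0])
        table = DecisionTable(X, labels)
        assert lower_approximation(X[0], table, 1, unit_stats(3)) == 0.0

    @pytest.mark.parametrize("cfg", ALL_CFGS, ids=lambda c: f"{c.similarity}-{c.aggregation}")
    def test_matches_literal_oracle(self, cfg, rng):
        s = unit_stats(3)
        table = random_table(rng)
        for x in table.X[:6]:
            up = upper_approximation(x, table, 1, s, cfg)
            lo = lower_approximation(x, table, 1, s, cfg)
            assert up == pytest.approx(oracle_upper(x, table, 1, s, cfg), abs=1e-12)
            assert lo == pytest.approx(oracle_lower(x, table, 1, s, cfg), abs=1e-12)

    def test_sandwich_lower_membership_upper(self):
        rng = np.random.default_rng(99)
        s = unit_stats(4)
        for _ in range(20):
            table = random_table(rng, n=10, d=4)
            for cfg in ALL_CFGS:
                for x, label in zip(table.X, table.labels):
                    mu = 1.0 if label == 1 else 0.0
                    lo = lower_approximation(x, table, 1, s, cfg)
                    up = upper_approximation(x, table, 1, s, cfg)
                    assert lo - 1e-12 <= mu <= up + 1e-12

    def test_upper_monotone_in_concept_members(self, rng):
        s = unit_stats(3)
        X = rng.random((10, 3))
        x = rng.random(3)
        prev = 0.0
        for n_members in range(1, 11):
            labels = np.array([1] * n_members + [0] * (10 - n_members))
            up = upper_approximation(x, DecisionTable(X, labels), 1, s)
            assert up >= prev - 1e-12
            prev = up


class TestAveragedFrua:
    def test_m1_equals_single_table_upper_bitwise(self, rng):
        s = unit_stats(4)
        X_pos, X_cand = rng.random((15, 4)), rng.random((9, 4))
        table = DecisionTable(np.vstack([X_pos, X_cand]),
                              np.r_[np.ones(15, int), np.zeros(9, int)])
        fr = averaged_frua(X_pos, X_cand, 1, 1, s, seed=3)
        singles = np.array([upper_approximation(x, table, 1, s) for x in X_cand])
        np.testing.assert_array_equal(fr.scores, singles)

    def test_candidate_identical_to_positive_scores_one_when_m1(self, rng):
        s = unit_stats(3)
        X_pos = rng.random((8, 3))
        X_cand = np.vstack([X_pos[4], rng.random((4, 3))])
        fr = averaged_frua(X_pos, X_cand, 1, 1, s, seed=0)
        assert fr.scores[0] == 1.0

    def test_candidate_identical_to_positive_at_least_one_over_m(self, rng):
        s = unit_stats(3)
        X_pos = rng.random((20, 3))
        X_cand = np.vstack([X_pos[0], rng.random((9, 3))])
        fr = averaged_frua(X_pos, X_cand, 4, 2, s, seed=1)
        assert fr.scores[0] >= 1.0 / 4 - 1e-12

    @pytest.mark.parametrize("cfg", ALL_CFGS, ids=lambda c: f"{c.similarity}-{c.aggregation}")
    def test_grouped_scores_match_exhaustive_oracle(self, cfg, rng):
        """20 positives, 10 candidates, m=2, n=2: element-wise mean of the
        two per-table brute-force degree vectors."""
        s = unit_stats(3)
        X_pos, X_cand = rng.random((20, 3)), rng.random((10, 3))
        m, n, seed = 2, 2, 11
        fr = averaged_frua(X_pos, X_cand, m, n, s, cfg, seed=seed)
        # reproduce the seeded grouping, then brute-force each decision table
        expected = np.zeros(10)
        for pg in fr.positive_groups:
            for cg in fr.candidate_groups:
                table = DecisionTable(
                    np.vstack([X_pos[pg], X_cand[cg]]),
                    np.r_[np.ones(len(pg), int), np.zeros(len(cg), int)],
                )
                for ci in cg:
                    expected[ci] += oracle_upper(X_cand[ci], table, 1, s, cfg)
        np.testing.assert_allclose(fr.scores, expected / m, atol=1e-12)

    def test_scores_in_unit_interval(self, rng):
        s = unit_stats(5)
        fr = averaged_frua(rng.random((30, 5)), rng.random((25, 5)), 3, 4, s, seed=0)
        assert np.all((fr.scores >= 0) & (fr.scores <= 1))

    def test_empty_positives_rejected(self, rng):
        with pytest.raises(ValueError, match="empty positive"):
            averaged_frua(np.empty((0, 3)), rng.random((5, 3)), 1, 1, unit_stats(3))


class TestComplexityContract:
    def test_relation_matrix_cost_is_n_squared_times_attributes(self, rng):
        from pairsift.fuzzy_rough import (
            relation_matrix,
            reset_similarity_eval_count,
            similarity_eval_count,
        )
        table = random_table(rng, n=8, d=5)
        reset_similarity_eval_count()
        relation_matrix(table, unit_stats(5))
        assert similarity_eval_count() == 8 * 8 * 5
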