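import numpy as np
import pytest
from scipy.stats import hypergeom

import gradis
from gradis.feature_construction import PairFeatures
from gradis.io_formats import DataValidationError, TrainingError
from gradis.negative_selection import (
    enrichment_null_test,
    extract_negative_class,
    iterative_negative_scoring,
    partition_uncharacterized,
    PairScoreTable,
)


def _pairs(n, prefix="p"):
    return [(f"T{i % 3}", f"{prefix}{i}") for i in range(n)]


def _features_for(pairs, vectors):
    return PairFeatures(list(pairs), np.asarray(vectors, dtype=float), "euclidean", 3)


class TestPartition:
    def test_exact_division(self):
        subsets = partition_uncharacterized(_pairs(12), 4, seed=0)
        assert [len(s) for s in subsets] == [4, 4, 4]

    def test_remainder_goes_to_last_subset(self):
        subsets = partition_uncharacterized(_pairs(14), 4, seed=0)
        assert [len(s) for s in subsets] == [4, 4, 6]

    def test_union_is_input_and_subsets_disjoint(self):
        pool = _pairs(23)
        subsets = partition_uncharacterized(pool, 5, seed=1)
        flat = [p for s in subsets for p in s]
        assert len(flat) == len(set(flat)) == len(pool)
        assert set(flat) == set(pool)

    def test_too_small_pool_suggests_fallback(self):
        with pytest.raises(DataValidationError, match="random"):
            partition_uncharacterized(_pairs(7), 4, seed=0)

    def test_deterministic_and_order_independent(self):
        pool = _pairs(20)
        a = partition_uncharacterized(pool, 5, seed=3)
        b = partition_uncharacterized(list(reversed(pool)), 5, seed=3)
        assert a == b
        c = partition_uncharacterized(pool, 5, seed=4)
        assert a != c

    def test_benchmark_scale_subset_count(self):
        """An E. coli-shaped instance: floor(|U|/|P|) balanced subsets, here 80."""
        n_pos = 2066
        pool = [("T", f"g{i}") for i in range(80 * n_pos + 500)]
        subsets = partition_uncharacterized(pool, n_pos, seed=0)
        assert len(subsets) == 80
        assert all(len(s) == n_pos for s in subsets[:-1])
        assert len(subsets[-1]) == n_pos + 500


class TestIterativeScoring:
    def test_duplicated_training_negatives_score_zero(self):
        """Pairs identical in feature space to every iteration's negatives
        must end with score 0 under any consistent classifier."""
        pairs = [("T0", f"g{i}") for i in range(9)]
        feats = _features_for(pairs + [("T0", "pos")],
                              [[0, 0, 0]] * 9 + [[1, 1, 1]])
        subsets = [pairs[:3], pairs[3:6], pairs[6:]]

        def nearest_mean_stub(X, y):
            mu_pos = X[y > 0].mean(axis=0)
            mu_neg = X[y < 0].mean(axis=0)
            return lambda Z: np.where(
                np.linalg.norm(Z - mu_pos, axis=1) < np.linalg.norm(Z - mu_neg, axis=1), 1, -1
            )

        table = iterative_negative_scoring(feats, [("T0", "pos")], subsets,
                                           train_fn=nearest_mean_stub)
        assert all(s == 0 for s in table.scores.values())

    def test_max_attainable_score_counting(self):
        """With 3 subsets each pair is assessed in exactly 2 iterations, so
        an always-positive classifier yields score 2 everywhere."""
        pairs = _pairs(9)
        feats = _features_for(pairs + [("T9", "pos")], np.zeros((10, 3)))
        subsets = [pairs[:3], pairs[3:6], pairs[6:]]
        always_pos = lambda X, y: (lambda Z: np.ones(len(Z)))
        table = iterative_negative_scoring(feats, [("T9", "pos")], subsets,
                                           train_fn=always_pos)
        assert table.n_iterations == 3
        assert table.max_possible_score == 2
        assert set(table.scores.values()) == {2}
        own = iterative_negative_scoring(feats, [("T9", "pos")], subsets,
                                         train_fn=always_pos, score_own_iteration=True)
        assert own.max_possible_score == 3
        assert set(own.scores.values()) == {3}

    def test_classifier_failure_aborts_with_iteration_index(self):
        pairs = _pairs(9)
        feats = _features_for(pairs + [("T9", "pos")], np.zeros((10, 3)))
        subsets = [pairs[:3], pairs[3:6], pairs[6:]]
        calls = {"n": 0}

        def failing(X, y):
            if calls["n"] == 1:
                raise RuntimeError("boom")
            calls["n"] += 1
            return lambda Z: np.ones(len(Z))

        with pytest.raises(TrainingError, match="iteration 1"):
            iterative_negative_scoring(feats, [("T9", "pos")], subsets, train_fn=failing)

    def test_true_pairs_outscore_false_pairs(self, heldout_scoring):
        """The scheme's purpose: hidden true edges accumulate higher scores
        than pairs with no planted interaction."""
        _, _, hidden, res = heldout_scoring
        scores = res.score_table.scores
        true_scores = [scores[p] for p in hidden]
        false_scores = [s for p, s in scores.items() if p not in hidden]
        assert np.mean(true_scores) > np.mean(false_scores)
        assert np.median(true_scores) > res.score_table.n_iterations / 2

    def test_scores_bounded_and_total(self, heldout_scoring):
        data, observed_gold, _, res = heldout_scoring
        table = res.score_table
        unchar = observed_gold.uncharacterized_pairs(data.expr.gene_ids)
        assert set(table.scores) == set(unchar)
        assert all(0 <= s <= table.max_possible_score for s in table.scores.values())


class TestExtractNegativeClass:
    def test_zero_threshold_selects_zero_scores(self):
        table = PairScoreTable({("T", f"g{i}"): (0 if i < 10 else 3) for i in range(20)},
                               n_iterations=5, subset_assignment={})
        out = extract_negative_class(table, threshold=0)
        assert len(out) == 10 and all(table.scores[p] == 0 for p in out)

    def test_threshold_relaxed_to_reach_required_n(self):
        scores = {("T", "a"): 0, ("T", "b"): 0, ("T", "c"): 1,
                  ("T", "d"): 2, ("T", "e"): 2, ("T", "f"): 4}
        table = PairScoreTable(scores, n_iterations=5, subset_assignment={})
        out = extract_negative_class(table, threshold=0, required_n=5)
        assert len(out) == 5
        assert out == {p for p, s in scores.items() if s <= 2}

    def test_unreachable_required_n_errors(self):
        table = PairScoreTable({("T", "a"): 0}, n_iterations=3, subset_assignment={})
        with pytest.raises(DataValidationError):
            extract_negative_class(table, required_n=5)

    def test_mined_negatives_depleted_of_true_edges(self, heldout_scoring):
        """Zero-score pool contains a lower fraction of planted edges than a
        random same-size draw from the uncharacterized pool."""
        _, _, hidden, res = heldout_scoring
        zero = extract_negative_class(res.score_table)
        universe = sorted(res.score_table.scores)
        rng = np.random.default_rng(0)
        draw = {universe[i] for i in rng.choice(len(universe), len(zero), replace=False)}
        frac_mined = len(zero & hidden) / len(zero)
        frac_random = len(draw & hidden) / len(draw)
        assert frac_mined < frac_random
        assert not (zero & res.model.gold.positives)


class TestEnrichmentNullTest:
    def test_exact_truth_set_gives_minimal_p(self):
        universe = [("T", f"g{i}") for i in range(200)]
        truth = set(universe[:8])
        obs, null_max, p = enrichment_null_test(truth, truth, universe, n_random=500, seed=0)
        assert obs == 8
        assert p == 1 / 501

    def test_uniform_draw_matches_hypergeometric_mean(self):
        rng = np.random.default_rng(1)
        universe = [("T", f"g{i}") for i in range(400)]
        truth = set(universe[i] for i in rng.choice(400, 60, replace=False))
        draw = set(universe[i] for i in rng.choice(400, 50, replace=False))
        obs, null_max, p = enrichment_null_test(draw, truth, universe, n_random=1000, seed=2)
        expected = hypergeom.mean(400, 60, 50)  # = 50*60/400 = 7.5
        assert abs(obs - expected) < 4 * hypergeom.std(400, 60, 50)
        assert p > 0.01

    def test_universe_smaller_than_set_rejected(self):
        universe = [("T", "a")]
        with pytest.raises(DataValidationError):
            enrichment_null_test([("T", "a"), ("T", "b")], set(), universe)
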