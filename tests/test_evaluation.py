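import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

import gradis
from gradis.evaluation import (
    aupr,
    auc,
    balanced_cv_evaluate,
    combine_score_matrices,
    confidence_interval,
    mantel_correlation,
    per_tf_auc_distribution,
)
from gradis.io_formats import DataValidationError


from oracles import brute_force_auc


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_one_inversion_counts_three_of_four(self):
        assert auc([0.9, 0.3, 0.8, 0.2], [1, 1, 0, 0]) == 0.75

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(DataValidationError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_and_sklearn_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = rng.choice(np.round(rng.random(6), 2), size=n)  # with ties
            labels = np.zeros(n, int)
            labels[rng.choice(n, int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            got = auc(scores, labels)
            assert got == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
            assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestAupr:
    def test_perfect_ranker_scores_one(self):
        assert aupr([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_constant_ranker_scores_prevalence(self):
        assert aupr([0.4] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]) == pytest.approx(0.3)

    def test_hand_computed_step_sum(self):
        # thresholds descending: recall steps 1/3 at P=1, 1/3 at P=1, 1/3 at P=3/4
        got = aupr([0.9, 0.8, 0.7, 0.6, 0.5, 0.4], [1, 1, 0, 1, 0, 0])
        assert got == pytest.approx(1 / 3 + 1 / 3 + (3 / 4) / 3, abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(DataValidationError):
            aupr([0.1, 0.2], [0, 0])

    def test_matches_sklearn_average_precision(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(5, 40))
            scores = rng.normal(size=n)
            labels = (rng.random(n) < 0.3).astype(int)
            if labels.sum() == 0:
                labels[0] = 1
            assert aupr(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12
            )


class TestConfidenceInterval:
    def test_constant_input_degenerate_with_warning(self):
        with pytest.warns(UserWarning):
            lo, hi = confidence_interval([0.8] * 10)
        assert lo == hi == 0.8

    def test_two_point_arithmetic(self):
        from scipy.stats import norm
        lo, hi = confidence_interval([0.7, 0.9])
        sd = np.std([0.7, 0.9], ddof=1)
        z = norm.ppf(0.975)
        assert lo == pytest.approx(0.8 - z * sd)
        assert hi == pytest.approx(0.8 + z * sd)

    def test_width_monotone_in_spread(self):
        widths = []
        for spread in (0.4, 0.2, 0.1, 0.05):
            lo, hi = confidence_interval([0.5 - spread, 0.5, 0.5 + spread])
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)


class TestBalancedCvEvaluate:
    def test_report_shape_and_ranges(self, tiny_fit):
        report = tiny_fit.evaluate(folds=5, repetitions=3, seed=0)
        assert len(report.per_run) == 3
        for _, a, p in report.per_run:
            assert 0 <= a <= 1 and 0 <= p <= 1
        assert report.ci_auc[0] <= report.mean_auc <= report.ci_auc[1]
        assert report.ci_aupr[0] <= report.mean_aupr <= report.ci_aupr[1]

    def test_deterministic_under_seed(self, tiny_fit):
        a = tiny_fit.evaluate(folds=5, repetitions=2, seed=9)
        b = tiny_fit.evaluate(folds=5, repetitions=2, seed=9)
        assert a.per_run == b.per_run
        assert a.held_out == b.held_out

    def test_every_pair_tested_exactly_once_per_repetition(self, tiny_fit):
        report = tiny_fit.evaluate(folds=5, repetitions=2, seed=1)
        positives = set(tiny_fit.model.gold.positives)
        negatives = set(tiny_fit.negatives)
        for records in report.held_out:
            tested = [(tf, g) for tf, g, _, _ in records]
            assert len(tested) == len(set(tested))
            assert set(tested) == positives | negatives

    def test_shuffled_labels_give_chance_auc(self, dream4_fit):
        """Randomly reassigning the positive labels among the evaluated
        pairs drives the mean AUC to 0.5 +/- 0.05."""
        rng = np.random.default_rng(5)
        pos = sorted(dream4_fit.model.gold.positives)
        neg_all = sorted(dream4_fit.negatives)
        neg = [neg_all[i] for i in rng.choice(len(neg_all), len(pos), replace=False)]
        union = pos + neg
        take = rng.choice(len(union), len(pos), replace=False)
        fake_pos = [union[i] for i in take]
        fake_neg = [union[i] for i in range(len(union)) if i not in set(take.tolist())]
        report = balanced_cv_evaluate(dream4_fit.features, fake_pos, fake_neg,
                                      folds=10, repetitions=3, seed=5,
                                      compute_per_tf=False)
        assert abs(report.mean_auc - 0.5) < 0.05

    def test_too_few_negatives_rejected(self, tiny_fit):
        pos = sorted(tiny_fit.model.gold.positives)
        with pytest.raises(DataValidationError):
            balanced_cv_evaluate(tiny_fit.features, pos, pos[:3], folds=3)


class TestPerTfAuc:
    def test_perfectly_ranked_tf_and_absent_tf(self):
        reps = [
            [("T1", "a", 0.9, 1), ("T1", "b", 0.8, 1), ("T1", "c", 0.1, 0),
             ("T2", "d", 0.2, 1)],  # T2 lacks negatives -> skipped
            [("T1", "e", 0.7, 1), ("T1", "f", 0.2, 0)],
        ]
        out = per_tf_auc_distribution(reps)
        assert out["T1"] == (1.0, 1.0, 1.0)
        assert "T2" not in out

    def test_global_auc_within_per_tf_extremes(self, dream4_fit):
        report = dream4_fit.evaluate(folds=10, repetitions=2, seed=2)
        assert report.per_tf, "expected at least one evaluable TF"
        means = [v[1] for v in report.per_tf.values()]
        assert min(means) - 1e-9 <= report.mean_auc <= max(means) + 1e-9


class TestMantel:
    @staticmethod
    def _random_distance_matrix(rng, n):
        from scipy.spatial.distance import pdist, squareform
        return squareform(pdist(rng.random((n, 3))))

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        a = self._random_distance_matrix(rng, 12)
        r, p = mantel_correlation(a, 2 * a, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_independent_matrices_uncorrelated(self):
        rng = np.random.default_rng(1)
        a = self._random_distance_matrix(rng, 20)
        b = self._random_distance_matrix(rng, 20)
        r, p = mantel_correlation(a, b, n_perm=199, seed=1)
        assert abs(r) < 0.35
        assert p > 0.05

    def test_r_matches_skbio_oracle(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(2)
        a = self._random_distance_matrix(rng, 15)
        b = a + self._random_distance_matrix(rng, 15)
        r, _ = mantel_correlation(a, b, n_perm=9, seed=0)
        r_ref, _, _ = skbio_stats.mantel(a, b, permutations=9, alternative="greater")
        assert r == pytest.approx(r_ref, abs=1e-12)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(DataValidationError):
            mantel_correlation(bad, bad)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        a = self._random_distance_matrix(rng, 10)
        b = self._random_distance_matrix(rng, 10)
        assert mantel_correlation(a, b, 99, seed=5) == mantel_correlation(a, b, 99, seed=5)


class TestCombineScoreMatrices:
    def _mat(self, values, tfs=("T1", "T2"), genes=("g1", "g2", "g3")):
        return pd.DataFrame(values, index=list(tfs), columns=list(genes))

    def test_single_matrix_scaled_by_max(self):
        m = self._mat([[1.0, 2.0, 4.0], [0.0, 3.0, 2.0]])
        out = combine_score_matrices([m])
        pd.testing.assert_frame_equal(out, m / 4.0)

    def test_identical_matrices_unchanged(self):
        m = self._mat([[1.0, 2.0, 4.0], [0.0, 3.0, 2.0]])
        out = combine_score_matrices([m, m.copy()])
        pd.testing.assert_frame_equal(out, m / 4.0)

    def test_min_rule_implements_conjunction(self):
        m1 = self._mat([[4.0, 0.0, 0.0], [0.0, 0.0, 0.0]])  # (T1,g1) high in m1
        m2 = self._mat([[0.2, 2.0, 0.0], [0.0, 0.0, 0.0]])  # but low in m2
        out = combine_score_matrices([m1, m2])
        t = 0.5
        assert out.loc["T1", "g1"] < t  # fails the conjunction at threshold t
        assert (out.to_numpy() >= 0).all() and (out.to_numpy() <= 1).all()

    def test_axis_mismatch_rejected(self):
        m1 = self._mat([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        m2 = self._mat([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], tfs=("T1", "TX"))
        with pytest.raises(DataValidationError):
            combine_score_matrices([m1, m2])

    def test_all_zero_matrix_rejected(self):
        m1 = self._mat([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        z = self._mat(np.zeros((2, 3)))
        with pytest.raises(DataValidationError):
            combine_score_matrices([m1, z])
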