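"""Mining the negative class from uncharacterized TF-gene pairs.

Experimental gold standards record interactions, almost never their absence,
so the negative class must be inferred from the unlabelled pool (a
positive-unlabelled problem). The scheme: split the uncharacterized pairs
into floor(|U|/|P|) subsets of the positive-class size; in each iteration
train a classifier on positives (+1) vs one subset (-1) and classify the
remaining uncharacterized pairs, incrementing the score of each pair the
classifier calls positive. Pairs that finish with a zero score were never
mistaken for positives by any classifier and form the negative training
class; high-scoring pairs are candidate unreported interactions.

By default a pair is not scored by the iteration that used it as training
negatives, so the maximum attainable score is n_iterations - 1;
``score_own_iteration=True`` scores every pair with every classifier
(maximum = n_iterations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .feature_construction import PairFeatures
from .io_formats import DataValidationError, TrainingError

logger = logging.getLogger(__name__)

__all__ = [
    "PairScoreTable",
    "partition_uncharacterized",
    "iterative_negative_scoring",
    "extract_negative_class",
    "enrichment_null_test",
]

Pair = tuple[str, str]


@dataclass
class PairScoreTable:
    """Integer plausibility score per uncharacterized pair.

    A low score marks a likely non-interaction; ``subset_assignment`` maps
    each pair to the iteration in which it served as the negative class.
    """

    scores: dict[Pair, int]
    n_iterations: int
    subset_assignment: dict[Pair, int]
    score_own_iteration: bool = False

    @property
    def max_possible_score(self) -> int:
        return self.n_iterations if self.score_own_iteration else self.n_iterations - 1

    def pairs_with_score(self, *, at_most: int | None = None, at_least: int | None = None) -> set[Pair]:
        lo = -1 if at_least is None else at_least
        hi = self.max_possible_score + 1 if at_most is None else at_most
        return {p for p, s in self.scores.items() if lo <= s <= hi}


def partition_uncharacterized(
    uncharacterized: Iterable[Pair],
    n_positives: int,
    seed: int = 0,
) -> list[list[Pair]]:
    """Randomly partition the unlabelled pool into subsets of the positive-class size.

    Returns floor(|U|/|P|) disjoint subsets; each has exactly ``n_positives``
    members except the last, which absorbs the remainder. The permutation is
    drawn under ``seed`` after a deterministic sort, so the partition is
    reproducible regardless of input ordering.
    """
    pool = sorted(set(uncharacterized))
    if n_positives < 1:
        raise DataValidationError("need at least one positive pair")
    n_subsets = len(pool) // n_positives
    if n_subsets < 2:
        raise DataValidationError(
            f"only {len(pool)} uncharacterized pairs for {n_positives} positives "
            "(need at least 2x); consider sampling negatives at random instead"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pool))
    shuffled = [pool[i] for i in perm]
    subsets = [shuffled[t * n_positives:(t + 1) * n_positives] for t in range(n_subsets - 1)]
    subsets.append(shuffled[(n_subsets - 1) * n_positives:])
    return subsets


def iterative_negative_scoring(
    features: PairFeatures,
    positives: Sequence[Pair],
    subsets: Sequence[Sequence[Pair]],
    *,
    train_fn: Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]] | None = None,
    svm_config: dict | None = None,
    inner_cv: bool = False,
    score_own_iteration: bool = False,
    seed: int = 0,
) -> PairScoreTable:
    """Run the iterative scoring scheme and return the score table.

    For each subset t a fresh classifier is trained on positives (+1) versus
    subset t (-1) and applied to every uncharacterized pair outside subset t
    (or to all pairs if ``score_own_iteration``); positively classified pairs
    gain one point. ``train_fn(X, y) -> predict`` may inject a custom
    classifier (used in tests); the default is the RBF-kernel SVM, with
    ``inner_cv`` enabling tenfold grid selection of (C, gamma) per iteration.
    """
    from .classification import train_classifier  # deferred: avoids import cycle

    positives = list(positives)
    all_unchar: list[Pair] = [p for subset in subsets for p in subset]
    if len(set(all_unchar)) != len(all_unchar):
        raise DataValidationError("subsets overlap")

    if train_fn is None:
        config = dict(svm_config or {})

        def train_fn(X: np.ndarray, y: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
            model = train_classifier(
                X, y, backend="svm_rbf", hyperparameters=config,
                seed=seed, tune=inner_cv,
            )
            return lambda Z: np.sign(model.decision_scores(Z))

    X_pos = features.rows(positives)
    scores = {p: 0 for p in all_unchar}
    assignment = {p: t for t, subset in enumerate(subsets) for p in subset}
    unchar_arr = np.array(all_unchar, dtype=object)
    X_unchar = features.rows(all_unchar)
    subset_of = np.array([assignment[p] for p in all_unchar])

    for t, subset in enumerate(subsets):
        X_neg = features.rows(subset)
        X_train = np.vstack([X_pos, X_neg])
        y_train = np.concatenate([np.ones(len(positives)), -np.ones(len(subset))])
        try:
            predict = train_fn(X_train, y_train)
            test_mask = np.ones(len(all_unchar), bool) if score_own_iteration else subset_of != t
            preds = predict(X_unchar[test_mask])
        except Exception as exc:
            raise TrainingError(f"classifier failed in iteration {t}: {exc}") from exc
        for pair in unchar_arr[test_mask][np.asarray(preds) > 0]:
            scores[tuple(pair)] += 1
        logger.debug("iteration %d/%d: %d pairs classified positive",
                     t + 1, len(subsets), int(np.sum(np.asarray(preds) > 0)))

    return PairScoreTable(scores, len(subsets), assignment, score_own_iteration)


def extract_negative_class(
    table: PairScoreTable,
    threshold: int = 0,
    required_n: int | None = None,
) -> set[Pair]:
    """Pairs with score <= threshold: the mined negative training class.

    If fewer than ``required_n`` pairs qualify, the threshold is relaxed one
    unit at a time (each relaxation logged) until satisfied.
    """
    t = threshold
    while True:
        selected = {p for p, s in table.scores.items() if s <= t}
        if required_n is None or len(selected) >= required_n:
            if t > threshold:
                logger.warning("negative-class threshold relaxed from %d to %d "
                               "to reach %d pairs", threshold, t, required_n)
            if not selected:
                raise DataValidationError(
                    "no pairs at or below the score threshold; negative class is empty"
                )
            return selected
        if t >= table.max_possible_score:
            raise DataValidationError(
                f"cannot reach required_n={required_n} negatives even at the "
                f"maximum threshold ({len(selected)} available)"
            )
        t += 1


def enrichment_null_test(
    high_score_pairs: Iterable[Pair],
    truth_edges: Iterable[Pair],
    universe: Iterable[Pair],
    n_random: int = 1000,
    seed: int = 0,
) -> tuple[int, int, float]:
    """Permutation test: are high-scoring pairs enriched for true interactions?

    Draws ``n_random`` uniform same-size sets from the universe and counts
    their overlaps with the truth edges; the p-value is
    (1 + #{null >= observed}) / (n_random + 1).

    Returns
    -------
    (observed_hits, null_max, p_value)
    """
    high = set(high_score_pairs)
    truth = set(truth_edges)
    universe = sorted(set(universe))
    if not high <= set(universe):
        raise DataValidationError("high-score pairs must be a subset of the universe")
    if len(high) > len(universe):
        raise DataValidationError("universe smaller than the high-score set")
    observed = len(high & truth)
    truth_mask = np.array([p in truth for p in universe])
    rng = np.random.default_rng(seed)
    null = np.empty(n_random, dtype=int)
    for i in range(n_random):
        draw = rng.choice(len(universe), size=len(high), replace=False)
        null[i] = int(truth_mask[draw].sum())
    p = (1 + int(np.sum(null >= observed))) / (n_random + 1)
    return observed, int(null.max()), p
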