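"""The GRADIS model: supervised GRN inference from graph-distance profiles.

Usage mirrors the fit/results idiom of statistical modelling packages::

    import gradis

    data = gradis.make_benchmark_fixture("dream4_like", seed=0)
    model = gradis.GRADIS(data.expr, data.gold, k=30)
    res = model.fit(seed=0)
    print(res.summary())
    report = res.evaluate(folds=10, repetitions=10, seed=0)
    edges = res.predict()          # ranked (tf, target, score) edge list

The model object holds the data and configuration; ``fit`` runs sample
clustering, pair featurization, iterative negative-class mining and final
classifier training, returning a :class:`GRADISResults` that carries the
fitted classifier, the pair score table, the mined negatives, and
evaluation/prediction methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from . import classification, evaluation, feature_construction, negative_selection
from .io_formats import (
    DataValidationError,
    ExpressionMatrix,
    GoldStandard,
    read_expression,
    read_gold_standard,
)
from .sample_clustering import CentroidProfiles, cluster_samples, default_k

__all__ = ["GRADIS", "GRADISResults"]

Pair = tuple[str, str]


class GRADIS:
    """Supervised gene-regulatory-network inference model.

    Parameters
    ----------
    expression : ExpressionMatrix
        Genes x samples expression data.
    gold : GoldStandard
        Known TF->gene interactions (positive class) and the TF list.
    k : int, optional
        Number of sample clusters; defaults to min(50, n_samples // 2).
    metric : {'euclidean', 'manhattan'}
        Point-distance metric of the graph-distance feature.
    backend : {'svm_rbf', 'random_forest'}
        Final classifier.
    target_universe : iterable of str, optional
        Restrict candidate targets to this gene set (default: all genes in
        the expression matrix).
    score_own_iteration : bool
        Score each uncharacterized pair with every iteration's classifier,
        including the one that used it as training negatives.
    inner_cv : bool
        Tenfold grid selection of (C, gamma) inside each scoring iteration.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        gold: GoldStandard,
        *,
        k: int | None = None,
        metric: str = "euclidean",
        backend: str = "svm_rbf",
        hyperparameters: dict | None = None,
        target_universe: Iterable[str] | None = None,
        score_own_iteration: bool = False,
        inner_cv: bool = False,
        standardize_samples: bool = False,
    ) -> None:
        missing = sorted(gold.tf_ids - set(expression.gene_ids))
        if missing:
            raise DataValidationError(f"TFs absent from the expression matrix: {missing[:10]}")
        for tf, g in gold.positives:
            if g not in expression._gene_index:
                raise DataValidationError(f"gold-standard target {g!r} absent from expression matrix")
        self.expression = expression
        self.gold = gold
        self.k = int(k) if k is not None else default_k(expression.n_samples)
        self.metric = metric
        self.backend = backend
        self.hyperparameters = hyperparameters
        self.target_universe = sorted(set(target_universe)) if target_universe is not None else None
        self.score_own_iteration = bool(score_own_iteration)
        self.inner_cv = bool(inner_cv)
        self.standardize_samples = bool(standardize_samples)

    @classmethod
    def from_files(
        cls,
        expression_path,
        tf_list_path,
        gold_standard_path,
        **kwargs,
    ) -> "GRADIS":
        """Build the model from DREAM-dialect files."""
        expr = read_expression(expression_path)
        gold = read_gold_standard(gold_standard_path, tf_list_path)
        return cls(expr, gold, **kwargs)

    def fit(
        self,
        *,
        seed: int = 0,
        restarts: int = 10,
        negative_threshold: int = 0,
        required_negatives: int | None = None,
    ) -> "GRADISResults":
        """Run the full pipeline and return fitted results.

        Stages: (1) k-means sample clustering; (2) graph-distance
        featurization of the positive and uncharacterized pairs; (3)
        iterative positive-unlabelled scoring and zero-score negative-class
        extraction; (4) final classifier training on all positives plus an
        equal-size random sample of mined negatives. All randomness derives
        from ``seed``.
        """
        seed = int(seed)
        centroids = cluster_samples(
            self.expression, self.k, seed=seed, restarts=restarts,
            standardize_samples=self.standardize_samples,
        )
        positives = sorted(self.gold.positives)
        uncharacterized = self.gold.uncharacterized_pairs(
            self.expression.gene_ids, self.target_universe
        )
        features = feature_construction.featurize_pairs(
            centroids, positives + uncharacterized, self.metric
        )
        subsets = negative_selection.partition_uncharacterized(
            uncharacterized, len(positives), seed=seed + 1
        )
        score_table = negative_selection.iterative_negative_scoring(
            features, positives, subsets,
            svm_config=self.hyperparameters,
            inner_cv=self.inner_cv,
            score_own_iteration=self.score_own_iteration,
            seed=seed,
        )
        required = required_negatives
        if required is None:
            required = len(positives)  # never train on fewer negatives than positives
        negatives = negative_selection.extract_negative_class(
            score_table, threshold=negative_threshold, required_n=required
        )
        negatives -= self.gold.known_negatives  # avoid duplicating known labels
        negatives_sorted = sorted(negatives | self.gold.known_negatives)

        rng = np.random.default_rng(np.random.SeedSequence([seed % 2**31, 2]))
        take = rng.choice(len(negatives_sorted), size=min(len(positives), len(negatives_sorted)),
                          replace=False)
        train_neg = [negatives_sorted[i] for i in take]
        X = np.vstack([features.rows(positives), features.rows(train_neg)])
        y = np.concatenate([np.ones(len(positives)), -np.ones(len(train_neg))])
        clf = classification.train_classifier(
            X, y, backend=self.backend, hyperparameters=self.hyperparameters,
            seed=seed, metric=self.metric, k=self.k,
        )
        return GRADISResults(
            model=self,
            centroids=centroids,
            features=features,
            score_table=score_table,
            negatives=set(negatives_sorted),
            training_negatives=train_neg,
            classifier=clf,
            seed=seed,
        )


@dataclass
class GRADISResults:
    """Fitted GRADIS pipeline: classifier, mined negatives and diagnostics."""

    model: GRADIS
    centroids: CentroidProfiles
    features: feature_construction.PairFeatures
    score_table: negative_selection.PairScoreTable
    negatives: set[Pair]
    training_negatives: list[Pair]
    classifier: classification.ClassifierModel
    seed: int
    _report: evaluation.EvaluationReport | None = field(default=None, repr=False)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        gold = self.model.gold
        n_unchar = len(self.score_table.scores)
        lines = [
            "GRADIS fit summary",
            "=" * 52,
            f"{'genes x samples':<28}{self.model.expression.n_genes} x {self.model.expression.n_samples}",
            f"{'TFs':<28}{len(gold.tf_ids)}",
            f"{'positive pairs':<28}{gold.n_positives}",
            f"{'uncharacterized pairs':<28}{n_unchar}",
            f"{'clusters k':<28}{self.model.k}",
            f"{'feature length k(k-1)/2':<28}{self.classifier.feature_dim}",
            f"{'metric':<28}{self.model.metric}",
            f"{'backend':<28}{self.classifier.backend}",
            f"{'scoring iterations':<28}{self.score_table.n_iterations}",
            f"{'zero/low-score negatives':<28}{len(self.negatives)}",
            f"{'seed':<28}{self.seed}",
        ]
        if self._report is not None:
            r = self._report
            lines += [
                "-" * 52,
                f"{'CV mean AUC':<28}{r.mean_auc:.4f}  (95% CI {r.ci_auc[0]:.4f}-{r.ci_auc[1]:.4f})",
                f"{'CV mean AUPR':<28}{r.mean_aupr:.4f}  (95% CI {r.ci_aupr[0]:.4f}-{r.ci_aupr[1]:.4f})",
            ]
        return "\n".join(lines)

    # -- evaluation --------------------------------------------------------
    def evaluate(
        self,
        *,
        folds: int = 10,
        repetitions: int = 10,
        seed: int | None = None,
        balanced_test: bool = False,
    ) -> evaluation.EvaluationReport:
        """Balanced repeated cross-validation on positives vs mined negatives."""
        report = evaluation.balanced_cv_evaluate(
            self.features,
            sorted(self.model.gold.positives),
            sorted(self.negatives),
            folds=folds,
            repetitions=repetitions,
            seed=self.seed if seed is None else int(seed),
            backend=self.model.backend,
            hyperparameters=self.model.hyperparameters,
            balanced_test=balanced_test,
        )
        self._report = report
        return report

    # -- prediction --------------------------------------------------------
    def predict(
        self,
        tf_ids: Iterable[str] | None = None,
        gene_universe: Iterable[str] | None = None,
        *,
        exclude_training: bool = True,
    ) -> pd.DataFrame:
        """Score candidate (tf, gene) pairs; returns a ranked edge list."""
        exclusions: set[Pair] = set()
        if exclude_training:
            exclusions = set(self.model.gold.positives) | set(self.training_negatives)
        universe = gene_universe
        if universe is None:
            universe = self.model.target_universe or self.model.expression.gene_ids
        return classification.predict_network(
            self.classifier,
            self.centroids,
            tf_ids if tf_ids is not None else sorted(self.model.gold.tf_ids),
            universe,
            exclusions,
        )

    def candidate_interactions(self, min_score: int | None = None) -> pd.DataFrame:
        """High-scoring uncharacterized pairs from the mining stage —
        candidate unreported interactions (tf, gene, score), best first."""
        if min_score is None:
            min_score = max(1, self.score_table.max_possible_score - 5)
        rows = [(tf, g, s) for (tf, g), s in self.score_table.scores.items() if s >= min_score]
        return pd.DataFrame(rows, columns=["tf", "gene", "score"]).sort_values(
            ["score", "tf", "gene"], ascending=[False, True, True]
        ).reset_index(drop=True)
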