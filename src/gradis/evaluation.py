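"""Evaluation protocol: balanced repeated cross-validation, AUC/AUPR with
normal-fit confidence intervals, per-TF (local) AUC distributions, the
Mantel test for distance-structure concordance, and the wisdom-of-crowds
score-matrix combiner.

The class imbalance of GRN gold standards (far more negatives than
positives) is handled at training time only: each CV training split uses
all of its positives plus an equal-size uniform sample of its negatives,
while held-out folds are scored unbalanced so AUC/AUPR reflect the real
prevalence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .feature_construction import PairFeatures
from .io_formats import DataValidationError

__all__ = [
    "auc",
    "aupr",
    "confidence_interval",
    "EvaluationReport",
    "balanced_cv_evaluate",
    "per_tf_auc_distribution",
    "mantel_correlation",
    "combine_score_matrices",
]

Pair = tuple[str, str]


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DataValidationError("scores and labels must be 1-D of equal length")
    if not np.all(np.isfinite(scores)):
        raise DataValidationError("scores contain NaN/inf")
    labels = np.where(labels > 0, 1, 0)
    return scores, labels


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank statistic.

    Equals the probability that a random positive outscores a random
    negative, with ties counted one half (the Mann-Whitney form).
    """
    scores, labels = _check_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataValidationError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties with half credit
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aupr(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve by step-wise summation.

    Precision and recall are evaluated at every distinct score threshold
    (ties grouped) and the area is sum over steps of precision x delta-recall
    — no linear interpolation between PR points. A constant ranker scores
    the positive prevalence; a perfect ranker scores 1.
    """
    scores, labels = _check_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise DataValidationError("AUPR requires at least one positive")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    # threshold group boundaries: positions where the score strictly drops
    boundaries = np.flatnonzero(np.diff(s)) + 1
    cut_points = np.concatenate([boundaries, [len(s)]])
    tp = np.cumsum(y)[cut_points - 1]
    precision = tp / cut_points
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def confidence_interval(stats: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Normal-fit confidence interval for repeated-run statistics.

    Fits a normal distribution to the run values and returns
    mean +/- z_{(1+level)/2} * sd (sample standard deviation). Constant
    input yields a degenerate interval with a warning.
    """
    x = np.asarray(stats, dtype=float)
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise DataValidationError("need at least two finite run statistics")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        warnings.warn("all run statistics identical; confidence interval is degenerate",
                      stacklevel=2)
        return (mean, mean)
    z = float(norm.ppf(0.5 + level / 2))
    return (mean - z * sd, mean + z * sd)


@dataclass
class EvaluationReport:
    """Cross-validation performance summary.

    ``per_run`` holds one (run, auc, aupr) triple per repetition;
    ``held_out`` retains the pooled held-out (tf, gene, score, label)
    records per repetition for per-TF analysis and ROC plotting.
    """

    per_run: list[tuple[int, float, float]]
    mean_auc: float
    mean_aupr: float
    ci_auc: tuple[float, float]
    ci_aupr: tuple[float, float]
    per_tf: dict[str, tuple[float, float, float]] | None = None
    held_out: list[list[tuple[str, str, float, int]]] | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            "Cross-validation evaluation",
            "=" * 46,
            f"{'repetitions':<24}{len(self.per_run)}",
            f"{'mean AUC':<24}{self.mean_auc:.4f}  (95% CI {self.ci_auc[0]:.4f}-{self.ci_auc[1]:.4f})",
            f"{'mean AUPR':<24}{self.mean_aupr:.4f}  (95% CI {self.ci_aupr[0]:.4f}-{self.ci_aupr[1]:.4f})",
            "-" * 46,
            f"{'run':>4}{'AUC':>10}{'AUPR':>10}",
        ]
        lines += [f"{r:>4}{a:>10.4f}{p:>10.4f}" for r, a, p in self.per_run]
        if self.per_tf:
            lines.append("-" * 46)
            lines.append(f"per-TF AUC over {len(self.per_tf)} evaluable TFs "
                         f"(median of means {np.median([v[1] for v in self.per_tf.values()]):.3f})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "per_run": [{"run": r, "auc": a, "aupr": p} for r, a, p in self.per_run],
            "mean_auc": self.mean_auc,
            "mean_aupr": self.mean_aupr,
            "ci_auc": list(self.ci_auc),
            "ci_aupr": list(self.ci_aupr),
            "per_tf": {tf: {"min": v[0], "mean": v[1], "max": v[2]}
                       for tf, v in (self.per_tf or {}).items()} or None,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path

    def plot_roc(self, ax=None):
        """ROC curves of the pooled held-out scores, one per repetition."""
        if not self.held_out:
            raise DataValidationError("held-out scores were not retained")
        import matplotlib.pyplot as plt
        from sklearn.metrics import roc_curve

        if ax is None:
            _, ax = plt.subplots()
        for rep, records in enumerate(self.held_out):
            scores = [r[2] for r in records]
            labels = [r[3] for r in records]
            fpr, tpr, _ = roc_curve(labels, scores)
            ax.plot(fpr, tpr, alpha=0.6, lw=1)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"ROC, {len(self.held_out)} repetitions (mean AUC {self.mean_auc:.3f})")
        return ax


def balanced_cv_evaluate(
    features: PairFeatures,
    positives: Sequence[Pair],
    negatives: Sequence[Pair],
    *,
    folds: int = 10,
    repetitions: int = 10,
    seed: int = 0,
    backend: str = "svm_rbf",
    hyperparameters: dict | None = None,
    balanced_test: bool = False,
    compute_per_tf: bool = True,
) -> EvaluationReport:
    """Repeated stratified k-fold CV with class-balanced training splits.

    Per repetition: positives and negatives are independently shuffled and
    split into ``folds`` folds. For each fold the classifier trains on the
    other folds' positives plus an equal-size uniform random sample of their
    negatives, then scores the whole held-out fold (unbalanced by default).
    Held-out scores are pooled per repetition into one AUC and one AUPR.
    """
    from .classification import train_classifier  # deferred import cycle

    positives = sorted(set(positives))
    negatives = sorted(set(negatives))
    if len(negatives) < len(positives):
        raise DataValidationError(
            f"need at least as many negatives ({len(negatives)}) as positives ({len(positives)})"
        )
    if len(positives) < folds or len(negatives) < folds:
        raise DataValidationError(
            f"cannot form {folds} folds from {len(positives)} positives / {len(negatives)} negatives"
        )

    per_run: list[tuple[int, float, float]] = []
    held_out_all: list[list[tuple[str, str, float, int]]] = []
    for rep in range(repetitions):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, rep]))
        pos = [positives[i] for i in rng.permutation(len(positives))]
        neg = [negatives[i] for i in rng.permutation(len(negatives))]
        pos_folds = np.array_split(np.arange(len(pos)), folds)
        neg_folds = np.array_split(np.arange(len(neg)), folds)
        records: list[tuple[str, str, float, int]] = []
        for f in range(folds):
            test_pos = [pos[i] for i in pos_folds[f]]
            test_neg = [neg[i] for i in neg_folds[f]]
            train_pos = [p for j, fold in enumerate(pos_folds) if j != f for p in (pos[i] for i in fold)]
            train_neg_pool = [p for j, fold in enumerate(neg_folds) if j != f for p in (neg[i] for i in fold)]
            if not test_pos or not test_neg:
                raise DataValidationError(f"fold {f} lost a class; use fewer folds")
            take = rng.choice(len(train_neg_pool), size=len(train_pos), replace=False)
            train_neg = [train_neg_pool[i] for i in take]
            X_train = np.vstack([features.rows(train_pos), features.rows(train_neg)])
            y_train = np.concatenate([np.ones(len(train_pos)), -np.ones(len(train_neg))])
            model = train_classifier(X_train, y_train, backend=backend,
                                     hyperparameters=hyperparameters, seed=seed + rep)
            if balanced_test:
                take_t = rng.choice(len(test_neg), size=min(len(test_pos), len(test_neg)),
                                    replace=False)
                test_neg = [test_neg[i] for i in take_t]
            test_pairs = test_pos + test_neg
            test_labels = [1] * len(test_pos) + [0] * len(test_neg)
            test_scores = model.decision_scores(features.rows(test_pairs))
            records += [(tf, g, float(s), int(lab))
                        for (tf, g), s, lab in zip(test_pairs, test_scores, test_labels)]
        scores = [r[2] for r in records]
        labels = [r[3] for r in records]
        per_run.append((rep, auc(scores, labels), aupr(scores, labels)))
        held_out_all.append(records)

    aucs = [a for _, a, _ in per_run]
    auprs = [p for _, _, p in per_run]
    report = EvaluationReport(
        per_run=per_run,
        mean_auc=float(np.mean(aucs)),
        mean_aupr=float(np.mean(auprs)),
        ci_auc=confidence_interval(aucs) if len(aucs) > 1 else (aucs[0], aucs[0]),
        ci_aupr=confidence_interval(auprs) if len(auprs) > 1 else (auprs[0], auprs[0]),
        held_out=held_out_all,
    )
    if compute_per_tf:
        report.per_tf = per_tf_auc_distribution(held_out_all)
    return report


def per_tf_auc_distribution(
    held_out: list[list[tuple[str, str, float, int]]],
) -> dict[str, tuple[float, float, float]]:
    """Local view: (min, mean, max) AUC per TF over repetitions.

    For each repetition and TF, AUC is computed over that TF's held-out
    pairs when both classes are present; a TF missing a class in a
    repetition is skipped for that repetition, and a TF never evaluable is
    absent from the output.
    """
    per_tf_runs: dict[str, list[float]] = {}
    for records in held_out:
        by_tf: dict[str, list[tuple[float, int]]] = {}
        for tf, _g, s, lab in records:
            by_tf.setdefault(tf, []).append((s, lab))
        for tf, rows in by_tf.items():
            labs = [lab for _, lab in rows]
            if 0 < sum(labs) < len(labs):
                per_tf_runs.setdefault(tf, []).append(
                    auc([s for s, _ in rows], labs)
                )
    return {
        tf: (float(np.min(v)), float(np.mean(v)), float(np.max(v)))
        for tf, v in sorted(per_tf_runs.items())
    }


def mantel_correlation(
    dist_a: np.ndarray,
    dist_b: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test between two distance matrices.

    Pearson correlation of the vectorized upper triangles; the permutation
    p-value simultaneously permutes the rows and columns of the second
    matrix ``n_perm`` times (one-sided, greater).
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise DataValidationError("need two square matrices of identical shape")
    for name, m in (("first", a), ("second", b)):
        if not np.allclose(m, m.T):
            raise DataValidationError(f"{name} matrix is not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise DataValidationError(f"{name} matrix has a nonzero diagonal")
    iu = np.triu_indices(a.shape[0], k=1)
    va, vb = a[iu], b[iu]
    if va.std() == 0 or vb.std() == 0:
        raise DataValidationError("degenerate (constant) distance matrix")
    r = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(a.shape[0])
        r_perm = np.corrcoef(va, b[np.ix_(perm, perm)][iu])[0, 1]
        if r_perm >= r:
            count += 1
    return r, (count + 1) / (n_perm + 1)


def combine_score_matrices(matrices: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Wisdom-of-crowds combiner for TF x gene score matrices.

    Each matrix is scaled by its global maximum; the combined score of a
    pair is the minimum of its scaled scores, so "above threshold t in all
    matrices" is exactly "combined score >= t" and ROC/PR sweeps over the
    conjunction are well defined. Output entries lie in [0, 1].
    """
    if len(matrices) < 1:
        raise DataValidationError("need at least one score matrix")
    ref = matrices[0]
    scaled = []
    for m in matrices:
        if not (m.index.equals(ref.index) and m.columns.equals(ref.columns)):
            raise DataValidationError("score matrices must share identical TF/gene axes")
        vals = m.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise DataValidationError("score matrices must be non-negative and finite")
        top = vals.max()
        if top <= 0:
            raise DataValidationError("all-zero score matrix cannot be scaled")
        scaled.append(vals / top)
    return pd.DataFrame(np.min(scaled, axis=0), index=ref.index, columns=ref.columns)
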