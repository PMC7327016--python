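"""Final pair classifier: RBF-kernel SVM (default) or random forest.

The SVM scores a pair p with f(p) = sum_i alpha_i K(p_i, p) over the support
pairs, K a Gaussian kernel; the sign of the score is the predicted label and
its magnitude ranks candidate edges for ROC/PR evaluation. Features are
bounded by construction ([0, sqrt(2)] Euclidean, [0, 2] Manhattan), so no
additional standardization is applied.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
import sklearn
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from .feature_construction import featurize_pairs
from .io_formats import DataValidationError, TrainingError, ranked_edge_list
from .sample_clustering import CentroidProfiles

__all__ = ["ClassifierModel", "train_classifier", "predict_network",
           "save_model", "load_model"]

BACKENDS = ("svm_rbf", "random_forest")

SVM_DEFAULTS = {"C": 1.0, "gamma": "scale"}  # gamma = 1/(n_features * var(X))
RF_DEFAULTS = {"n_trees": 500, "max_depth": None}
SVM_TUNING_GRID = {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 0.01, 0.1, 1.0]}


@dataclass
class ClassifierModel:
    """A fitted pair classifier plus the metadata needed to apply it safely.

    ``feature_dim`` must match the k(k-1)/2 graph features the model was
    trained on; ``metric`` and ``k`` record the feature construction so a
    model cannot silently score incompatible features.
    """

    backend: str
    hyperparameters: dict
    estimator: object
    feature_dim: int
    metric: str | None = None
    k: int | None = None
    library_version: str = field(default_factory=lambda: sklearn.__version__)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Continuous margin score per row; sign(score) is the predicted label."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.feature_dim:
            raise DataValidationError(
                f"feature dimension {X.shape[1] if X.ndim == 2 else X.shape} "
                f"does not match the model's {self.feature_dim}"
            )
        if self.backend == "svm_rbf":
            return self.estimator.decision_function(X)
        # RF: class-+1 probability recentred at zero so sign = label.
        proba = self.estimator.predict_proba(X)
        pos_col = int(np.argmax(self.estimator.classes_ == 1))
        return proba[:, pos_col] - 0.5

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        s = self.decision_scores(X)
        return np.where(s > 0, 1, -1)


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    backend: str = "svm_rbf",
    hyperparameters: dict | None = None,
    seed: int = 0,
    *,
    tune: bool = False,
    metric: str | None = None,
    k: int | None = None,
) -> ClassifierModel:
    """Fit the pair classifier on a labelled (+1/-1) training set.

    ``tune=True`` selects (C, gamma) for the SVM by tenfold cross-validated
    grid search; otherwise the fixed defaults (C=1, gamma='scale') are used.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise DataValidationError("features must be a 2-D matrix")
    if len(y) != X.shape[0]:
        raise DataValidationError(f"{X.shape[0]} feature rows but {len(y)} labels")
    if not np.all(np.isfinite(X)):
        raise DataValidationError("features contain NaN/inf")
    classes = set(np.unique(y).tolist())
    if not classes <= {-1, 1} or len(classes) != 2:
        raise DataValidationError(f"labels must contain both +1 and -1, got {sorted(classes)}")
    if backend not in BACKENDS:
        raise DataValidationError(f"backend must be one of {BACKENDS}, got {backend!r}")

    hp = dict(hyperparameters or {})
    try:
        if backend == "svm_rbf":
            params = {**SVM_DEFAULTS, **hp}
            est = SVC(kernel="rbf", C=params["C"], gamma=params["gamma"])
            if tune:
                search = GridSearchCV(SVC(kernel="rbf"), SVM_TUNING_GRID, cv=10,
                                      scoring="roc_auc", n_jobs=1)
                search.fit(X, y)
                params = {**params, **search.best_params_}
                est = SVC(kernel="rbf", C=params["C"], gamma=params["gamma"])
            est.fit(X, y)
        else:
            params = {**RF_DEFAULTS, **hp}
            est = RandomForestClassifier(
                n_estimators=params["n_trees"], max_depth=params["max_depth"],
                max_features="sqrt", random_state=int(seed) % (2**32), n_jobs=1,
            )
            est.fit(X, y)
    except DataValidationError:
        raise
    except Exception as exc:
        raise TrainingError(f"{backend} training failed: {exc}") from exc

    return ClassifierModel(backend, params, est, X.shape[1], metric=metric, k=k)


def predict_network(
    model: ClassifierModel,
    centroids: CentroidProfiles,
    tf_ids: Iterable[str],
    gene_universe: Iterable[str] | None = None,
    exclusions: Iterable[tuple[str, str]] = (),
    *,
    include_self_pairs: bool = False,
):
    """Score every (tf, gene) candidate pair and return a ranked edge list.

    The candidate set is tf_ids x gene_universe minus self-pairs and
    ``exclusions`` (typically the training pairs). Because the graph-distance
    feature is TF<->gene symmetric, (A, B) and (B, A) receive equal scores
    when both are TFs; direction comes from restricting sources to tf_ids.
    """
    if model.metric is None:
        raise DataValidationError("model lacks the feature metric; cannot featurize pairs")
    if model.k is not None and model.k != centroids.k:
        raise DataValidationError(f"model was trained at k={model.k}, centroids have k={centroids.k}")
    genes = sorted(set(gene_universe if gene_universe is not None else centroids.gene_ids))
    excl = set(exclusions)
    pairs = [
        (tf, g)
        for tf in sorted(set(tf_ids))
        for g in genes
        if (include_self_pairs or g != tf) and (tf, g) not in excl
    ]
    if not pairs:
        raise DataValidationError("no candidate pairs left after exclusions")
    feats = featurize_pairs(centroids, pairs, model.metric)
    scores = model.decision_scores(feats.X)
    return ranked_edge_list((tf, g, float(s)) for (tf, g), s in zip(pairs, scores))


def save_model(model: ClassifierModel, path: str | Path) -> Path:
    """Serialize the fitted model with its metadata to a single file."""
    path = Path(path)
    joblib.dump(
        {
            "backend": model.backend,
            "hyperparameters": model.hyperparameters,
            "estimator": model.estimator,
            "feature_dim": model.feature_dim,
            "metric": model.metric,
            "k": model.k,
            "library_version": model.library_version,
            "python_version": sys.version,
        },
        path,
    )
    return path


def load_model(path: str | Path) -> ClassifierModel:
    blob = joblib.load(path)
    return ClassifierModel(
        blob["backend"], blob["hyperparameters"], blob["estimator"],
        blob["feature_dim"], blob["metric"], blob["k"], blob["library_version"],
    )
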