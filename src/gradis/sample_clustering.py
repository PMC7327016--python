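"""Sample compression by k-means clustering.

The number of samples determines the number of downstream features, so the
samples (not the genes) are clustered into k groups and each gene's profile
is summarised by its expression at the k cluster centroids: the reduced
profile x_g = (x_g^1, ..., x_g^k).

Raw k-means labels are arbitrary, and downstream feature coordinates are
indexed by cluster, so clusters are relabelled canonically (descending size,
ties by lexicographically smallest member sample id) to make feature indices
reproducible. One clustering is computed per dataset and shared by all pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io_formats import DataValidationError, ExpressionMatrix, GoldStandard

logger = logging.getLogger(__name__)

__all__ = ["CentroidProfiles", "cluster_samples", "choose_k_report",
           "write_centroids", "read_centroids"]


@dataclass
class CentroidProfiles:
    """Genes x k matrix of expression at the k-means sample-cluster centroids.

    ``centroids[:, j]`` is the per-gene mean over the samples assigned to
    cluster j; ``assignment`` maps each sample id to its cluster index.
    """

    gene_ids: list[str]
    k: int
    centroids: np.ndarray
    assignment: dict[str, int]
    seed: int

    def __post_init__(self) -> None:
        if self.centroids.shape != (len(self.gene_ids), self.k):
            raise DataValidationError(
                f"centroid matrix shape {self.centroids.shape} != "
                f"({len(self.gene_ids)}, {self.k})"
            )
        sizes = np.bincount(list(self.assignment.values()), minlength=self.k)
        if (sizes == 0).any():
            raise DataValidationError("every cluster must be nonempty")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    def profile(self, gene_id: str) -> np.ndarray:
        """The k-dimensional centroid profile of one gene."""
        try:
            return self.centroids[self._gene_index[gene_id]]
        except KeyError:
            raise DataValidationError(f"unknown gene id: {gene_id!r}") from None

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(list(self.assignment.values()), minlength=self.k)


def cluster_samples(
    expr: ExpressionMatrix,
    k: int,
    *,
    seed: int = 0,
    restarts: int = 10,
    standardize_samples: bool = False,
) -> CentroidProfiles:
    """Cluster the samples into k groups and return centroid profiles.

    Each sample is a point in gene-dimensional Euclidean space; Lloyd's
    algorithm is run ``restarts`` times and the solution with the lowest
    within-cluster sum of squares is kept. Centroids are recomputed as exact
    per-cluster means of the final assignment. ``standardize_samples``
    z-scores each sample vector before clustering (the assignment changes;
    the returned centroids are always means of the raw data).

    Raises
    ------
    DataValidationError
        If k < 2 or k exceeds the number of samples.
    """
    n_samples = expr.n_samples
    if k < 2:
        raise DataValidationError(f"k must be at least 2, got {k}")
    if k > n_samples:
        raise DataValidationError(f"k={k} exceeds the number of samples ({n_samples})")

    points = expr.values.T  # samples x genes
    if standardize_samples:
        mu = points.mean(axis=1, keepdims=True)
        sd = points.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        points = (points - mu) / sd

    km = KMeans(n_clusters=k, n_init=restarts, max_iter=300, tol=1e-6,
                random_state=int(seed) % (2**32))
    labels = km.fit_predict(points)

    # Canonical relabelling: descending cluster size, ties broken by the
    # lexicographically smallest member sample id.
    order = sorted(
        range(k),
        key=lambda c: (-int(np.sum(labels == c)),
                       min(s for s, l in zip(expr.sample_ids, labels) if l == c)),
    )
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[l] for l in labels])

    centroids = np.empty((expr.n_genes, k))
    for c in range(k):
        centroids[:, c] = expr.values[:, labels == c].mean(axis=1)
    assignment = {s: int(l) for s, l in zip(expr.sample_ids, labels)}
    logger.info("clustered %d samples into k=%d (WCSS best of %d restarts)",
                n_samples, k, restarts)
    return CentroidProfiles(list(expr.gene_ids), k, centroids, assignment, int(seed))


def default_k(n_samples: int) -> int:
    """Default cluster count: min(50, n_samples // 2).

    Performance saturates at about k = 50 on dense benchmark compendia;
    for small sample counts half the samples keeps clusters populated.
    """
    return max(2, min(50, n_samples // 2))


def choose_k_report(
    expr: ExpressionMatrix,
    gold: GoldStandard,
    k_grid: list[int],
    *,
    seed: int = 0,
    folds: int = 5,
    repetitions: int = 2,
    backend: str = "svm_rbf",
) -> pd.DataFrame:
    """Advisory sweep: mean cross-validated AUC of the full pipeline per k.

    Runs the whole method (clustering, features, negative mining, balanced
    CV) at reduced repetitions for each k in ``k_grid``. A failing k is
    recorded with its error message rather than aborting the sweep.
    """
    from .model import GRADIS  # deferred: model builds on this module

    rows = []
    for k in k_grid:
        try:
            res = GRADIS(expr, gold, k=int(k), backend=backend).fit(seed=seed)
            report = res.evaluate(folds=folds, repetitions=repetitions, seed=seed)
            rows.append({"k": int(k), "mean_auc": report.mean_auc, "error": ""})
        except Exception as exc:  # noqa: BLE001 - sweep records failures
            rows.append({"k": int(k), "mean_auc": np.nan, "error": str(exc)})
    return pd.DataFrame(rows)


def write_centroids(profiles: CentroidProfiles, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(profiles.centroids, index=profiles.gene_ids,
                      columns=[f"c{j + 1}" for j in range(profiles.k)])
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_centroids(path: str | Path, assignment: dict[str, int] | None = None,
                   seed: int = 0) -> CentroidProfiles:
    """Read a centroid TSV written by :func:`write_centroids`.

    The sample assignment is not stored in the TSV; a placeholder assignment
    (one synthetic sample per cluster) is used unless one is supplied.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    k = df.shape[1]
    if assignment is None:
        assignment = {f"_c{j}": j for j in range(k)}
    return CentroidProfiles(list(df.index.astype(str)), k, df.to_numpy(dtype=float),
                            assignment, seed)
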