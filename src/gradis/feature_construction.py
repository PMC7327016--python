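"""Graph-distance features for TF-gene pairs.

A pair of [0,1]-rescaled k-dimensional centroid profiles (x_TF, x_G) is a
set of k points (x_TF^i, x_G^i) in the unit square. The feature vector is
the upper triangle (diagonal excluded) of the complete weighted graph on
those points, i.e. all C(k,2) pairwise point distances

    w(n_i, n_j)   = sqrt((x_TF^i - x_TF^j)^2 + (x_G^i - x_G^j)^2)   (euclidean)
    w_m(n_i, n_j) = |x_TF^i - x_TF^j| + |x_G^i - x_G^j|             (manhattan)

in row-major i<j order: (1,2), (1,3), ..., (1,k), (2,3), ..., (k-1,k).
The feature is symmetric under swapping the TF and the gene; direction is
carried entirely by which ordered pairs are labelled positive.

An expression-concatenation baseline feature (both raw profiles rescaled
and stacked, length 2m over all m samples) is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io_formats import DataValidationError
from .sample_clustering import CentroidProfiles

__all__ = [
    "Metric",
    "rescale_profile",
    "pair_feature",
    "pair_points",
    "point_distance_matrix",
    "expression_pair_feature",
    "PairFeatures",
    "featurize_pairs",
    "feature_length",
]

Metric = Literal["euclidean", "manhattan"]
_PDIST_METRIC = {"euclidean": "euclidean", "manhattan": "cityblock"}


def _check_metric(metric: str) -> str:
    if metric not in _PDIST_METRIC:
        raise DataValidationError(f"metric must be 'euclidean' or 'manhattan', got {metric!r}")
    return metric


def rescale_profile(profile: Sequence[float] | np.ndarray) -> np.ndarray:
    """Affine min-max rescaling of one profile to [0, 1].

    A constant profile carries no positional information; it maps to the
    centre of the interval (all 0.5) rather than fabricating an extreme.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1:
        raise DataValidationError("profile must be a 1-D vector")
    if not np.all(np.isfinite(x)):
        raise DataValidationError("profile contains NaN/inf")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def pair_points(tf: np.ndarray, g: np.ndarray) -> np.ndarray:
    """The k points (x_TF^i, x_G^i) of a pair, as a (k, 2) array."""
    tf = np.asarray(tf, dtype=float)
    g = np.asarray(g, dtype=float)
    if tf.shape != g.shape or tf.ndim != 1:
        raise DataValidationError(
            f"profiles must be 1-D of equal length, got {tf.shape} vs {g.shape}"
        )
    if tf.size < 2:
        raise DataValidationError("need k >= 2 cluster coordinates")
    return np.column_stack([tf, g])


def pair_feature(tf: np.ndarray, g: np.ndarray, metric: Metric = "euclidean") -> np.ndarray:
    """Graph-distance feature vector of one (TF, gene) pair.

    Both arguments are rescaled k-vectors; the result has length k(k-1)/2
    (the condensed order of :func:`scipy.spatial.distance.pdist` is exactly
    the row-major upper triangle).
    """
    _check_metric(metric)
    return pdist(pair_points(tf, g), metric=_PDIST_METRIC[metric])


def point_distance_matrix(tf: np.ndarray, g: np.ndarray, metric: Metric = "euclidean") -> np.ndarray:
    """Full symmetric k x k point-distance matrix of a pair (zero diagonal)."""
    return squareform(pair_feature(tf, g, metric))


def feature_length(k: int) -> int:
    """Number of graph-distance features for k clusters: k(k-1)/2."""
    return k * (k - 1) // 2


def expression_pair_feature(tf_raw: np.ndarray, g_raw: np.ndarray) -> np.ndarray:
    """Expression-concatenation baseline feature over all m samples.

    Each profile is min-max rescaled independently and the two halves are
    concatenated into a length-2m vector. Unlike the graph-distance feature
    this is ordered: swapping the arguments swaps the halves.
    """
    tf_raw = np.asarray(tf_raw, dtype=float)
    g_raw = np.asarray(g_raw, dtype=float)
    if tf_raw.shape != g_raw.shape or tf_raw.ndim != 1:
        raise DataValidationError(
            f"profiles must be 1-D of equal length, got {tf_raw.shape} vs {g_raw.shape}"
        )
    return np.concatenate([rescale_profile(tf_raw), rescale_profile(g_raw)])


@dataclass
class PairFeatures:
    """A batch of pair feature vectors with their pair identities.

    ``X[i]`` is the feature vector of ``pairs[i]``; rows follow the input
    pair order of :func:`featurize_pairs`.
    """

    pairs: list[tuple[str, str]]
    X: np.ndarray
    metric: str
    k: int

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.pairs):
            raise DataValidationError("feature matrix rows != number of pairs")
        self._index = {p: i for i, p in enumerate(self.pairs)}

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._index

    def rows(self, pairs: Iterable[tuple[str, str]]) -> np.ndarray:
        """Feature sub-matrix for the given pairs, in the given order."""
        try:
            idx = [self._index[p] for p in pairs]
        except KeyError as exc:
            raise DataValidationError(f"pair {exc.args[0]} has no features") from None
        return self.X[idx]


def featurize_pairs(
    centroids: CentroidProfiles,
    pairs: Sequence[tuple[str, str]],
    metric: Metric = "euclidean",
) -> PairFeatures:
    """Graph-distance feature matrix for a list of (tf, gene) pairs.

    Scaled profiles are computed once per gene and cached, so featurizing
    the full TF x gene universe costs one rescale per gene plus one pdist
    per pair.
    """
    _check_metric(metric)
    scaled: dict[str, np.ndarray] = {}

    def scaled_profile(gid: str) -> np.ndarray:
        if gid not in scaled:
            scaled[gid] = rescale_profile(centroids.profile(gid))
        return scaled[gid]

    n = len(pairs)
    X = np.empty((n, feature_length(centroids.k)))
    for i, (tf, g) in enumerate(pairs):
        X[i] = pair_feature(scaled_profile(tf), scaled_profile(g), metric)
    return PairFeatures(list(pairs), X, metric, centroids.k)
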