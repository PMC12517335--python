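"""K-means clustering of the embedding matrix.

The number of clusters follows the half-the-dataset heuristic
``k = floor(n / 2)`` by default; the fraction is configurable. Fitting uses
scikit-learn's Lloyd k-means (k-means++ seeding, best of ``restarts`` runs
by inertia, fixed random seed for reproducibility) followed by a short
polish loop that re-derives each centroid as the exact mean of its members
and reassigns points until the labelling is a strict Lloyd fixed point.
Empty clusters arising during the polish are repaired by moving in the
point farthest from its current centroid. Nearest-centroid ties break
toward the lower cluster index.

Distances are Euclidean throughout: the embedding space is Euclidean and
the within-cluster sum of squares (inertia) is the quantity k-means
minimizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .core_io import EmbeddingMatrix
from .errors import ParameterError

DEFAULT_SEED = 0
DEFAULT_RESTARTS = 5
DEFAULT_FRACTION = 0.5
_MAX_POLISH_ITER = 100


def choose_k(n: int, fraction: float = DEFAULT_FRACTION) -> int:
    """Number of clusters: ``floor(n * fraction)``, clamped to ``[1, n]``."""
    if n < 2:
        raise ParameterError(f"need at least 2 proteins to cluster, got {n}")
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    return min(max(int(np.floor(n * fraction)), 1), n)


@dataclass
class ClusterModel:
    """K-means output: labels, centroids, member-to-centroid distances."""

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    distances: np.ndarray
    inertia: float

    def members(self, label: int) -> np.ndarray:
        """Row indices assigned to cluster ``label``."""
        return np.flatnonzero(self.labels == label)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def _as_array(X) -> np.ndarray:
    if isinstance(X, EmbeddingMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def kmeans_fit(
    X,
    k: int,
    seed: int = DEFAULT_SEED,
    restarts: int = DEFAULT_RESTARTS,
) -> ClusterModel:
    """Fit k-means and return a :class:`ClusterModel`.

    Deterministic for fixed ``(X, k, seed, restarts)``. The returned model
    satisfies the Lloyd fixed-point property: every non-empty cluster's
    centroid is the mean of its members and every point sits in its nearest
    cluster (ties toward the lower index).
    """
    X = _as_array(X)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, n] = [1, {n}], got {k}")
    if restarts < 1:
        raise ParameterError(f"restarts must be >= 1, got {restarts}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        max_iter=300,
        tol=1e-4,
        random_state=seed,
        algorithm="lloyd",
    )
    with warnings.catch_warnings():
        # duplicate points (e.g. zero-noise data) can leave clusters empty;
        # the polish step below repairs that, so the warning is moot
        warnings.simplefilter("ignore", ConvergenceWarning)
        km.fit(X)
    labels, centroids = _polish(X, km.labels_.astype(int), km.cluster_centers_, k)
    diffs = X - centroids[labels]
    distances = np.sqrt(np.einsum("ij,ij->i", diffs, diffs))
    inertia = float(np.sum(distances**2))
    return ClusterModel(
        k=k, labels=labels, centroids=centroids, distances=distances, inertia=inertia
    )


def _polish(
    X: np.ndarray, labels: np.ndarray, centroids: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate exact Lloyd steps until the labelling is a fixed point."""
    centroids = centroids.copy()
    for _ in range(_MAX_POLISH_ITER):
        for j in range(k):
            members = labels == j
            if members.any():
                centroids[j] = X[members].mean(axis=0)
            else:
                # repair: hand the empty cluster the farthest point
                diffs = X - centroids[labels]
                far = int(np.argmax(np.einsum("ij,ij->i", diffs, diffs)))
                labels[far] = j
                centroids[j] = X[far]
        new_labels = np.argmin(cdist(X, centroids, "sqeuclidean"), axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return labels, centroids


def cluster_census(model: ClusterModel) -> dict[int, int]:
    """Map cluster size -> number of clusters of that size (incl. size 0)."""
    sizes = model.sizes()
    census: dict[int, int] = {}
    for s in sizes:
        census[int(s)] = census.get(int(s), 0) + 1
    return census
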