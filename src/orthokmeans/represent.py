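"""Representation step: residue pooling and PCA reduction.

Protein language models emit one vector per residue; the pipeline consumes
one fixed-length vector per protein. Pooling here is the arithmetic mean
over residue positions (the usual convention for this model family; exposed
as a config choice). Optional PCA reduces the embedding dimension before
clustering, trading accuracy for speed.

PCA is computed with an exact (full SVD) decomposition so results are
deterministic at the scales this package targets. The per-axis sign is
fixed by convention — the loading of largest magnitude on each principal
axis is made positive — and axes beyond the numerical rank of the centered
data are zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import EmbeddingMatrix
from .errors import EmptyInputError, ParameterError

#: Pooling operators available for per-residue embeddings.
POOLING_CHOICES = ("mean",)


def pool_mean(residue_vectors: np.ndarray) -> np.ndarray:
    """Mean-pool an ``L x p`` per-residue matrix into a single ``p``-vector."""
    rv = np.asarray(residue_vectors, dtype=float)
    if rv.ndim == 1:
        rv = rv[None, :]
    if rv.shape[0] == 0:
        raise EmptyInputError("cannot pool an empty residue matrix")
    if not np.all(np.isfinite(rv)):
        raise ParameterError("residue vectors contain non-finite values")
    return rv.mean(axis=0)


@dataclass
class PCAModel:
    """Exact PCA of column-centered data.

    ``components`` rows are unit principal axes (zero rows past the
    numerical rank); ``explained_variance`` is the per-axis variance with
    the ``n - 1`` denominator, non-increasing.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    rank: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.components.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, dtype=float) @ self.components + self.mean


def pca_fit(X: np.ndarray, n_components: int) -> PCAModel:
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= n_components <= min(n, p):
        raise ParameterError(
            f"n_components must be in [1, min(n, p)] = [1, {min(n, p)}], "
            f"got {n_components}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    # full SVD for determinism; randomized solvers are not worth it here
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(n, p) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    components = vt[:n_components].copy()
    explained = (s[:n_components] ** 2) / max(n - 1, 1)
    # zero-pad axes beyond the numerical rank: their direction is arbitrary
    for j in range(n_components):
        if j >= rank:
            components[j] = 0.0
            explained[j] = 0.0
            continue
        # sign convention: largest-magnitude loading positive
        lead = np.argmax(np.abs(components[j]))
        if components[j, lead] < 0:
            components[j] = -components[j]
    return PCAModel(mean=mean, components=components, explained_variance=explained, rank=rank)


def pca_reduce(X, n_components: int):
    """Project onto the top ``n_components`` principal axes.

    Accepts a raw ``n x p`` array or an :class:`EmbeddingMatrix` and returns
    the same kind, reduced to ``n x n_components``.
    """
    if isinstance(X, EmbeddingMatrix):
        return EmbeddingMatrix(list(X.ids), pca_reduce(X.values, n_components))
    X = np.asarray(X, dtype=float)
    model = pca_fit(X, n_components)
    return model.transform(X)
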