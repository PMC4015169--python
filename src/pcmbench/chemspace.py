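"""PCA projections of descriptor space and neighbourhood-behavior reports.

Encoded peptides or binding sites are centered, scaled to unit variance
(constant columns are dropped with a warning) and projected onto principal
components; component signs are fixed so the largest-magnitude loading of
each component is positive, making projections deterministic up to item
order.

Neighbourhood behavior — the Similar Property Principle that items close in
descriptor space have similar activities — is quantified as the ratio of
the mean absolute activity difference to each item's k nearest neighbors in
score space over the all-pairs mean absolute difference; ratios below 1
indicate that the descriptor space organizes the activity landscape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = ["PCAProjection", "pca_project", "neighbourhood_report", "ChemspacePCA"]


@dataclass
class PCAProjection:
    scores: np.ndarray  # items x components
    loadings: np.ndarray  # kept features x components
    variance_explained: np.ndarray
    kept_columns: np.ndarray
    centering: np.ndarray
    scaling: np.ndarray

    def __post_init__(self):
        ve = np.asarray(self.variance_explained, dtype=float)
        if np.any(ve < -1e-12) or np.any(np.diff(ve) > 1e-12) or ve.sum() > 1 + 1e-9:
            raise ValueError("variance_explained must be nonincreasing fractions")


def pca_project(encoded, n_components: int = 2) -> PCAProjection:
    """Project items x features onto unit-variance-scaled principal components."""
    X = np.asarray(encoded, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 items")
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns are constant; nothing to project")
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant column(s) before PCA")
    mu = X[:, keep].mean(axis=0)
    Xs = (X[:, keep] - mu) / sd[keep]
    n_components = max(1, min(n_components, Xs.shape[1], Xs.shape[0] - 1))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xs)
    loadings = pca.components_.T.copy()
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAProjection(scores=scores, loadings=loadings,
                         variance_explained=pca.explained_variance_ratio_.copy(),
                         kept_columns=np.flatnonzero(keep),
                         centering=mu, scaling=sd[keep])


def neighbourhood_report(projection: PCAProjection, activities,
                         k_neighbors: int = 5) -> dict:
    """k-NN activity-difference ratio in PCA score space.

    Returns the per-item mean |activity difference| to the ``k_neighbors``
    nearest items, the dataset mean of those, the all-pairs mean and their
    ratio.  A constant activity vector makes the ratio undefined; it is
    reported as 1.0 with ``degenerate=True``.
    """
    scores = projection.scores
    y = np.asarray(activities, dtype=float)
    n = scores.shape[0]
    if y.shape != (n,):
        raise ValueError("activities must align with the projected items")
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the number of items")
    diff = np.abs(y[:, None] - y[None, :])
    all_pairs_mean = float(diff[np.triu_indices(n, k=1)].mean())
    dist = np.linalg.norm(scores[:, None, :] - scores[None, :, :], axis=2)
    np.fill_diagonal(dist, np.inf)
    nn = np.argsort(dist, axis=1)[:, :k_neighbors]
    per_item = diff[np.arange(n)[:, None], nn].mean(axis=1)
    knn_mean = float(per_item.mean())
    degenerate = all_pairs_mean == 0
    ratio = 1.0 if degenerate else knn_mean / all_pairs_mean
    return {"per_item": per_item, "knn_mean": knn_mean,
            "all_pairs_mean": all_pairs_mean, "ratio": float(ratio),
            "k_neighbors": k_neighbors, "degenerate": bool(degenerate)}


class ChemspacePCA(TransformerMixin, BaseEstimator):
    """scikit-learn transformer wrapping :func:`pca_project`.

    Fitted attributes expose the projection (``projection_``) plus the usual
    ``components_`` / ``explained_variance_ratio_`` aliases.
    """

    def __init__(self, n_components=2):
        self.n_components = n_components

    def fit(self, X, y=None):
        self.projection_ = pca_project(X, n_components=self.n_components)
        self.components_ = self.projection_.loadings.T
        self.explained_variance_ratio_ = self.projection_.variance_explained
        return self

    def transform(self, X):
        proj = self.projection_
        X = np.asarray(X, dtype=float)[:, proj.kept_columns]
        return ((X - proj.centering) / proj.scaling) @ proj.loadings

    def fit_transform(self, X, y=None, **kwargs):
        self.fit(X)
        return self.projection_.scores
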