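"""Bray-Curtis dissimilarity and principal-coordinates ordination.

Samples are compared on their clade read-percentage profiles with
Bray-Curtis dissimilarity, BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i), and
ordinated by classical metric scaling (PCoA): eigendecomposition of the
double-centered squared dissimilarity matrix.  Taking Bray-Curtis as the
input to a "PCA" in the classical-scaling sense is the default; a plain
covariance PCA of the raw percentage matrix is available for comparison.
Negative eigenvalues (possible for non-Euclidean dissimilarities) are
reported as-is and excluded from variance-explained denominators.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between sample rows."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    sums = values.sum(axis=1)
    dead = np.flatnonzero(sums == 0)
    if dead.size:
        names = [str(matrix.index[i]) for i in dead]
        raise ValueError(f"all-zero abundance rows for samples: {names}")
    dm = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(dm, index=matrix.index, columns=matrix.index)


@dataclasses.dataclass
class Ordination:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    proportion_explained: np.ndarray  # retained axes, vs sum of positive eigenvalues


def pcoa(dm: pd.DataFrame, k: int = 2) -> Ordination:
    """Classical metric scaling of a dissimilarity matrix onto ``k`` axes."""
    ids = list(dm.index)
    D = dm.to_numpy(dtype=float)
    n = len(ids)
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the number of samples ({n})")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be symmetric")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = np.zeros((n, k))
    for axis in range(k):
        if eigvals[axis] > 0:
            v = eigvecs[:, axis] * np.sqrt(eigvals[axis])
            # deterministic sign: largest-magnitude coordinate positive
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            coords[:, axis] = v
    positive = eigvals[eigvals > 0].sum()
    proportion = np.where(eigvals[:k] > 0, eigvals[:k] / positive, 0.0) if positive else np.zeros(k)
    frame = pd.DataFrame(
        coords, index=ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return Ordination(frame, eigvals, proportion)


def pca_raw(matrix: pd.DataFrame, k: int = 2) -> Ordination:
    """Covariance PCA of the raw abundance matrix (comparison mode)."""
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = X @ eigvecs[:, :k]
    for axis in range(k):
        if coords[np.argmax(np.abs(coords[:, axis])), axis] < 0:
            coords[:, axis] = -coords[:, axis]
    positive = eigvals[eigvals > 0].sum()
    proportion = np.where(eigvals[:k] > 0, eigvals[:k] / positive, 0.0) if positive else np.zeros(k)
    frame = pd.DataFrame(coords, index=matrix.index, columns=[f"PC{i + 1}" for i in range(k)])
    return Ordination(frame, eigvals, proportion)


def group_separation(ordination: Ordination, groups: dict[str, str]) -> float:
    """Mean silhouette of the sample groups on the first two axes."""
    coords = ordination.coordinates.iloc[:, :2]
    missing = [s for s in coords.index if s not in groups]
    if missing:
        raise ValueError(f"samples without group labels: {missing}")
    labels = [groups[s] for s in coords.index]
    sizes = pd.Series(labels).value_counts()
    if (sizes == 0).any() or len(sizes) < 2:
        raise ValueError("need at least two non-empty groups")
    X = coords.to_numpy()
    if np.allclose(pdist(X), 0.0):
        raise ValueError("all samples are coincident; silhouette undefined")
    return float(silhouette_score(X, labels))
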