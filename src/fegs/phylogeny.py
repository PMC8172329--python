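"""From feature vectors to trees and clustering accuracy.

Pairwise cosine distances between (reduced) feature vectors feed an
agglomerative clustering with single or complete linkage; the resulting
dendrogram is exported as an ultrametric Newick tree, cut into k flat
clusters, and scored against taxonomic labels with the adjusted Rand
index.
"""

from __future__ import annotations

import re
from typing import Mapping, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.metrics import adjusted_rand_score


def cosine_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances: d(i, j) = 1 - cos(x_i, x_j), in [0, 2]."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(
            f"cosine distance undefined for all-zero rows at indices {zero.tolist()}"
        )
    D = squareform(pdist(X, metric="cosine"))
    np.fill_diagonal(D, 0.0)
    return D


def linkage_tree(D: np.ndarray, method: str = "single") -> np.ndarray:
    """Agglomerative clustering of a precomputed distance matrix.

    Returns the standard (N-1) x 4 linkage matrix (children, merge height,
    cluster size).  Only the monotone single/complete linkages are
    offered, so merge heights never invert.
    """
    if method not in ("single", "complete"):
        raise ValueError(f"method must be 'single' or 'complete', got {method!r}")
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError(f"expected a square distance matrix, got shape {D.shape}")
    if n < 2:
        raise ValueError("linkage requires at least 2 observations")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    return sch.linkage(squareform(D, checks=False), method=method)


def cut_tree(Z: np.ndarray, k: int) -> np.ndarray:
    """Flat clustering into k clusters by undoing the last k - 1 merges.

    Returns integer labels (0-based) in observation order.
    """
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    return sch.cut_tree(Z, n_clusters=k).ravel()


_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,']")


def _quote_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Ultrametric Newick string for a linkage matrix.

    Leaves sit at height 0; each branch length is the parent merge height
    minus the child's height.  Labels containing Newick metacharacters are
    quoted.
    """
    n = Z.shape[0] + 1
    if len(labels) != n:
        raise ValueError(f"need {n} labels, got {len(labels)}")
    height = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {i: _quote_label(str(labels[i])) for i in range(n)}
    for m, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        parent = n + m
        height[parent] = float(h)
        left = f"{node[a]}:{height[parent] - height[a]:.10g}"
        right = f"{node[b]}:{height[parent] - height[b]:.10g}"
        node[parent] = f"({left},{right})"
    return node[n + Z.shape[0] - 1] + ";"


def adjusted_rand_index(
    p1: Mapping[str, object], p2: Mapping[str, object]
) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    Partitions map sequence ID to cluster label; the ID sets must match.
    1 for identical partitions (up to label renaming), ~0 for chance
    agreement.
    """
    if set(p1) != set(p2):
        only1 = sorted(set(p1) - set(p2))
        only2 = sorted(set(p2) - set(p1))
        raise ValueError(
            f"partitions cover different IDs (only in first: {only1}, "
            f"only in second: {only2})"
        )
    ids = sorted(p1)
    a = [str(p1[i]) for i in ids]
    b = [str(p2[i]) for i in ids]
    return float(adjusted_rand_score(a, b))


class HierarchicalPhylogeny(BaseEstimator):
    """Cosine-distance agglomerative tree builder with flat-cut labels.

    Parameters
    ----------
    linkage : {"single", "complete"}, default "single"
    metric : {"cosine", "precomputed"}, default "cosine"
        With "precomputed", ``fit`` expects a square distance matrix.

    Attributes
    ----------
    distance_matrix_ : (n, n) ndarray
    linkage_matrix_ : (n-1, 4) ndarray
    """

    def __init__(self, linkage: str = "single", metric: str = "cosine"):
        self.linkage = linkage
        self.metric = metric

    def fit(self, X: np.ndarray, y=None) -> "HierarchicalPhylogeny":
        if self.metric == "cosine":
            self.distance_matrix_ = cosine_distance_matrix(X)
        elif self.metric == "precomputed":
            self.distance_matrix_ = np.asarray(X, dtype=float)
        else:
            raise ValueError(
                f"metric must be 'cosine' or 'precomputed', got {self.metric!r}"
            )
        self.linkage_matrix_ = linkage_tree(self.distance_matrix_, self.linkage)
        return self

    def fit_predict(self, X: np.ndarray, y=None, k: int = 2) -> np.ndarray:
        return self.fit(X).cut(k)

    def cut(self, k: int) -> np.ndarray:
        self._check_fitted()
        return cut_tree(self.linkage_matrix_, k)

    def to_newick(self, labels: Sequence[str]) -> str:
        self._check_fitted()
        return to_newick(self.linkage_matrix_, labels)

    def _check_fitted(self) -> None:
        if not hasattr(self, "linkage_matrix_"):
            raise RuntimeError("estimator is not fitted; call fit(X) first")
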