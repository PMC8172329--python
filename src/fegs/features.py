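"""Feature fusion and dimensionality reduction.

The full descriptor of a protein sequence concatenates three blocks::

    [ V_g (one eigenvalue per property) | V_a (AAC, 20) | V_d (DPC, 400) ]

With the full 158-property configuration this is a 578-dimensional vector.
A dataset becomes an (n_sequences x n_features) matrix whose rows follow
input order; PCA (column centering, optional unit-variance scaling, and a
deterministic sign convention) reduces it before distance computation.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .aaindex import STANDARD_AMINO_ACIDS, PropertySet
from .composition import DPC_ORDER, aac, dpc
from .graphical import graphical_features


class FEGSVectorizer(BaseEstimator, TransformerMixin):
    """Transform protein sequences into fused graphical + statistical vectors.

    Parameters
    ----------
    properties : PropertySet
        The physicochemical property indices; each contributes one
        graphical feature.  The canonical configuration has 158 indices,
        giving 158 + 20 + 400 = 578 output features.
    freq_mode : {"count", "relative"}, default "count"
        Dipeptide frequency convention used while extending the 3D paths.

    Attributes
    ----------
    n_features_out_ : int
        ``len(properties) + 420``, set by :meth:`fit`.

    The transformer is stateless apart from validation: sequences are
    encoded independently, so ``transform`` output is row-wise identical
    regardless of batching or order.
    """

    def __init__(self, properties: PropertySet, freq_mode: str = "count"):
        self.properties = properties
        self.freq_mode = freq_mode

    def fit(self, X: Sequence[str] | None = None, y=None) -> "FEGSVectorizer":
        if self.freq_mode not in ("count", "relative"):
            raise ValueError(
                f"freq_mode must be 'count' or 'relative', got {self.freq_mode!r}"
            )
        if len(self.properties) == 0:
            raise ValueError("property set is empty")
        self.n_features_out_ = len(self.properties) + 420
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        """Encode each sequence in ``X`` as one feature row."""
        if not hasattr(self, "n_features_out_"):
            self.fit()
        rows = [self._encode_one(seq) for seq in X]
        return np.vstack(rows) if rows else np.empty((0, self.n_features_out_))

    def _encode_one(self, sequence: str) -> np.ndarray:
        if len(sequence) < 2:
            raise ValueError(
                f"sequences must have length >= 2, got {len(sequence)}"
            )
        return np.concatenate(
            [
                graphical_features(sequence, self.properties, self.freq_mode),
                aac(sequence),
                dpc(sequence),
            ]
        )

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        g = [f"g{i + 1:03d}" for i in range(len(self.properties))]
        a = [f"aac_{aa}" for aa in STANDARD_AMINO_ACIDS]
        d = [f"dpc_{pair}" for pair in DPC_ORDER]
        return np.asarray(g + a + d, dtype=object)


def fegs_vector(
    sequence: str, properties: PropertySet, freq_mode: str = "count"
) -> np.ndarray:
    """Feature vector of a single sequence (thin wrapper over the transformer)."""
    return FEGSVectorizer(properties, freq_mode).fit().transform([sequence])[0]


def feature_matrix(
    sequences: Iterable[tuple[str, str]],
    properties: PropertySet,
    freq_mode: str = "count",
) -> pd.DataFrame:
    """Feature matrix of a dataset, indexed by sequence ID in input order."""
    pairs = list(sequences)
    ids = [sid for sid, _ in pairs]
    dupes = sorted({sid for sid in ids if ids.count(sid) > 1})
    if dupes:
        raise ValueError(f"duplicate sequence IDs: {dupes}")
    vec = FEGSVectorizer(properties, freq_mode).fit()
    X = vec.transform([seq for _, seq in pairs])
    return pd.DataFrame(X, index=pd.Index(ids, name="id"),
                        columns=vec.get_feature_names_out())


def pca_reduce(
    X: np.ndarray | pd.DataFrame,
    n_components: int,
    scale: bool = False,
) -> np.ndarray:
    """Scores on the top ``n_components`` principal components.

    Columns are centered (and optionally scaled to unit variance); the
    sign of each component is fixed so its largest-magnitude loading is
    positive, making scores reproducible across platforms.
    """
    A = np.asarray(X, dtype=float)
    n, d = A.shape
    if not 1 <= n_components <= min(n, d):
        raise ValueError(
            f"n_components must be in [1, {min(n, d)}], got {n_components}"
        )
    if scale:
        sd = A.std(axis=0, ddof=0)
        A = A / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(A)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(n_components):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, k] = -scores[:, k]
    return scores


def n_components_for_variance(
    X: np.ndarray | pd.DataFrame, threshold: float = 0.95
) -> int:
    """Smallest component count reaching the cumulative explained-variance
    threshold (the default target when no count is pinned)."""
    A = np.asarray(X, dtype=float)
    pca = PCA(svd_solver="full")
    pca.fit(A)
    cum = np.cumsum(pca.explained_variance_ratio_)
    return int(np.searchsorted(cum, threshold) + 1)
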