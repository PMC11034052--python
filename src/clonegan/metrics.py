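"""Clustering evaluation indices.

External indices (ARI, NMI) compare inferred labels against ground truth;
internal indices (silhouette coefficient, Calinski-Harabasz) score cluster
geometry in the embedding when no truth is available.  Computation is
delegated to scikit-learn with the edge-case conventions fixed here: NMI is
normalized by the arithmetic mean of the entropies, defined as 0 when
either partition is a single cluster while the partitions differ, and 1
when both are single-cluster and equal; Euclidean distance is used for the
internal indices.
"""

from __future__ import annotations

import numpy as np
from sklearn import metrics as _skm

from .model import LatentEmbedding


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    return a, b


def ari(a, b) -> float:
    """Adjusted Rand index (Hubert-Arabie): (Index - E[Index]) / (Max - E[Index])."""
    a, b = _check_pair(a, b)
    return float(_skm.adjusted_rand_score(a, b))


def nmi(a, b) -> float:
    """Normalized mutual information, arithmetic-mean normalization."""
    a, b = _check_pair(a, b)
    na, nb = len(set(a.tolist())), len(set(b.tolist()))
    if na == 1 or nb == 1:
        # both trivial and identical partitions -> perfect agreement
        return 1.0 if (na == nb == 1 and _partitions_equal(a, b)) else 0.0
    return float(_skm.normalized_mutual_info_score(a, b, average_method="arithmetic"))


def _partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    _, ia = np.unique(a, return_inverse=True)
    _, ib = np.unique(b, return_inverse=True)
    return bool(np.array_equal(ia, ib))


def internal_indices(
    Z: LatentEmbedding | np.ndarray, labels
) -> tuple[float, float]:
    """Mean silhouette coefficient and Calinski-Harabasz index.

    Requires at least two clusters; silhouette of an all-singleton
    labelling is 0 by convention.
    """
    Zm = Z.z_matrix if isinstance(Z, LatentEmbedding) else np.asarray(Z, float)
    if Zm.ndim == 1:
        Zm = Zm[:, None]
    labels = np.asarray(labels).ravel()
    if labels.size != Zm.shape[0]:
        raise ValueError("labels and embedding disagree on cell count")
    n_clusters = len(set(labels.tolist()))
    if n_clusters < 2:
        raise ValueError("internal indices need at least 2 clusters")
    if n_clusters == labels.size:
        # every cluster a singleton: silhouette 0 by convention, and the
        # within-cluster scatter is 0 so CH diverges
        return 0.0, float("inf")
    sil = float(_skm.silhouette_score(Zm, labels, metric="euclidean"))
    ch = float(_skm.calinski_harabasz_score(Zm, labels))
    return sil, ch
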