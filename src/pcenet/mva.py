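"""Quantile normalization and multivariate correlation clustering.

The post-hoc analysis of selected key proteins: expression profiles are
quantile normalized across samples, correlated pairwise, and clustered by
average linkage on 1 - r into a requested number of groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

__all__ = ["CorrelationClustering", "quantile_normalize", "correlation_cluster"]


@dataclass
class CorrelationClustering:
    """Leaf order, cluster labels, and the pairwise correlation grid."""

    order: list[str]
    labels: pd.Series  # protein -> cluster label (1..k)
    correlation: pd.DataFrame


def quantile_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the mean distribution.

    Each column's sorted values are replaced by the across-sample mean of
    order statistics; tied values within a column receive the mean of the
    reference values their positions span. Idempotent by construction.
    """
    data = X.data
    if data.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    M = data.to_numpy(dtype=float)
    reference = np.sort(M, axis=0).mean(axis=1)
    out = np.empty_like(M)
    for j in range(M.shape[1]):
        col = M[:, j]
        order = np.argsort(col, kind="stable")
        ref_by_rank = np.empty_like(reference)
        ref_by_rank[order] = reference
        # ties: average the reference values spanned by equal input values
        _, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=ref_by_rank)
        counts = np.bincount(inv)
        out[:, j] = (sums / counts)[inv]
    return ExpressionMatrix(
        pd.DataFrame(out, index=data.index, columns=data.columns)
    )


def correlation_cluster(
    X: ExpressionMatrix,
    key_proteins,
    n_clusters: int | None = None,
    cut_height: float | None = None,
    method: str = "pearson",
) -> CorrelationClustering:
    """Cluster key-protein profiles on 1 - correlation, average linkage.

    Exactly one of ``n_clusters`` / ``cut_height`` selects the flat
    clustering; a singleton key set returns a single trivial cluster.
    ``method`` is ``pearson`` (default) or ``spearman``. Row order of the
    input does not matter: proteins are sorted by ID first.
    """
    keys = sorted(set(key_proteins))
    missing = [p for p in keys if p not in X.data.index]
    if missing:
        raise ValueError(f"key proteins absent from the matrix: {missing[:10]}")
    sub = X.data.loc[keys].astype(float)
    if (sub.std(axis=1, ddof=1) == 0).any():
        flat = list(sub.index[sub.std(axis=1, ddof=1) == 0])
        raise ValueError(f"zero-variance key proteins: {flat[:10]}")
    corr = sub.T.corr(method=method)
    if len(keys) == 1:
        return CorrelationClustering(
            order=keys,
            labels=pd.Series([1], index=keys, name="cluster"),
            correlation=corr,
        )
    D = 1.0 - corr.to_numpy()
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(np.clip(D, 0.0, 2.0), checks=False), method="average")
    if n_clusters is not None:
        raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    elif cut_height is not None:
        raw = fcluster(Z, t=cut_height, criterion="distance")
    else:
        raise ValueError("specify n_clusters or cut_height")
    order = [keys[i] for i in leaves_list(Z)]
    # relabel clusters in order of first appearance along the leaf order
    first_seen: dict[int, int] = {}
    for p in order:
        c = int(raw[keys.index(p)])
        if c not in first_seen:
            first_seen[c] = len(first_seen) + 1
    labels = pd.Series(
        [first_seen[int(raw[i])] for i in range(len(keys))],
        index=keys,
        name="cluster",
    )
    return CorrelationClustering(order=order, labels=labels, correlation=corr)
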