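"""Unsupervised hierarchical clustering of the secreted-protein matrix.

Rows (proteins) are z-score scaled, then rows and columns are clustered
agglomeratively (default: Euclidean distance, average linkage).  The
column dendrogram is the object of interest: with a batch offset larger
than the within-batch variation, its top split separates the batches.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator

from .containers import LogIntensityMatrix

logger = logging.getLogger(__name__)


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """(x - row mean) / row sample SD; constant rows map to all zeros."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning("%d constant row(s) z-scored to zeros", int(flat.sum()))
    sd = sd.where(~flat, 1.0)
    z = values.sub(mean, axis=0).div(sd, axis=0)
    z[flat] = 0.0
    return z


@dataclass
class ClusterResult:
    """Row/column leaf orderings, linkage trees, and the z-scored matrix."""

    zscored: pd.DataFrame
    row_order: np.ndarray
    col_order: np.ndarray
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None

    def top_column_split(self) -> dict[str, int]:
        """Sample -> {0, 1} labels from cutting the column tree into 2."""
        if self.col_linkage is None:
            return {s: 0 for s in self.zscored.columns}
        labels = hierarchy.fcluster(self.col_linkage, t=2, criterion="maxclust")
        return {s: int(l) - 1 for s, l in zip(self.zscored.columns, labels)}

    def linkage_frame(self, axis: str = "col") -> pd.DataFrame:
        """Flat merge table: node_id, child_a, child_b, height, n_leaves."""
        Z = self.col_linkage if axis == "col" else self.row_linkage
        n = (self.zscored.shape[1] if axis == "col" else self.zscored.shape[0])
        if Z is None:
            return pd.DataFrame(columns=["node_id", "child_a", "child_b",
                                         "height", "n_leaves"])
        return pd.DataFrame({
            "node_id": np.arange(n, n + len(Z)),
            "child_a": Z[:, 0].astype(int),
            "child_b": Z[:, 1].astype(int),
            "height": Z[:, 2],
            "n_leaves": Z[:, 3].astype(int),
        })


def _linkage(mat: np.ndarray, metric: str, method: str) -> np.ndarray | None:
    if mat.shape[0] < 2:
        return None
    dist = pdist(mat, metric=metric)
    return hierarchy.linkage(dist, method=method)


def hier_cluster(values: pd.DataFrame, metric: str = "euclidean",
                 method: str = "average") -> ClusterResult:
    """Cluster rows and columns of an already z-scored matrix."""
    if values.isna().values.any():
        raise ValueError("clustering requires a matrix with no missing values")
    row_Z = _linkage(values.to_numpy(), metric, method)
    col_Z = _linkage(values.to_numpy().T, metric, method)
    row_order = (hierarchy.leaves_list(row_Z) if row_Z is not None
                 else np.arange(values.shape[0]))
    col_order = (hierarchy.leaves_list(col_Z) if col_Z is not None
                 else np.arange(values.shape[1]))
    return ClusterResult(values, row_order, col_order, row_Z, col_Z)


class HierarchicalClusterer(BaseEstimator):
    """Z-score rows, then hierarchically cluster rows and columns.

    Attributes set by :meth:`fit`: ``result_`` (:class:`ClusterResult`),
    ``row_order_``, ``col_order_``.
    """

    def __init__(self, metric: str = "euclidean", method: str = "average",
                 zscore: bool = True):
        self.metric = metric
        self.method = method
        self.zscore = zscore

    def fit(self, X: LogIntensityMatrix | pd.DataFrame, y=None):
        values = X.values if isinstance(X, LogIntensityMatrix) else X
        if self.zscore:
            values = zscore_rows(values)
        self.result_ = hier_cluster(values, self.metric, self.method)
        self.row_order_ = self.result_.row_order
        self.col_order_ = self.result_.col_order
        return self

    def plot_heatmap(self, path) -> None:
        """Clustered heatmap PNG (optional output; requires matplotlib)."""
        import seaborn as sns

        r = self.result_
        g = sns.clustermap(
            r.zscored,
            row_linkage=r.row_linkage, col_linkage=r.col_linkage,
            cmap="vlag", center=0, xticklabels=True, yticklabels=False,
        )
        g.savefig(path, dpi=120)
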