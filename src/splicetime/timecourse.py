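"""Time-course clustering of PSI/PIR matrices and per-cluster summaries.

Rows (splicing events) are clustered by k-means (Lloyd iterations, Euclidean
distance, best of several random restarts by within-cluster sum of squares).
The elbow diagnostic reports WSS over a range of k; cluster centroids are in
turn used to cluster the timepoints hierarchically, ordering the columns of
heatmap exports. k is never auto-selected: the elbow curve is a diagnostic,
and the caller chooses k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import norm
from sklearn.cluster import KMeans

from .matrix import SplicingMatrix

logger = logging.getLogger(__name__)

DEFAULT_RESTARTS = 25
DEFAULT_SEED = 42


@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series  # row label -> cluster id (1-based)
    centroids: pd.DataFrame  # k x timepoints
    wss: float
    seed: int
    restarts: int

    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


def drop_incomplete_rows(matrix: SplicingMatrix) -> SplicingMatrix:
    """Remove rows containing any missing cell (required before k-means)."""
    complete = matrix.values.dropna(axis=0, how="any")
    n_dropped = len(matrix.values) - len(complete)
    if n_dropped:
        logger.info("dropped %d row(s) with missing values", n_dropped)
    return SplicingMatrix(values=complete, metric=matrix.metric, pseudo=matrix.pseudo)


def _as_complete_array(matrix: SplicingMatrix) -> pd.DataFrame:
    df = matrix.values
    if df.isna().any().any():
        raise ValueError("matrix contains missing values; drop_incomplete_rows first")
    if df.empty:
        raise ValueError("matrix has no rows")
    return df


def kmeans_cluster(
    matrix: SplicingMatrix,
    k: int,
    seed: int = DEFAULT_SEED,
    restarts: int = DEFAULT_RESTARTS,
) -> ClusterResult:
    """k-means with ``restarts`` random initializations, deterministic per seed."""
    df = _as_complete_array(matrix)
    if not 1 <= k <= len(df):
        raise ValueError(f"k={k} outside [1, {len(df)} rows]")
    km = KMeans(
        n_clusters=k,
        n_init=restarts,
        random_state=seed,
        algorithm="lloyd",
    ).fit(df.to_numpy())
    assignments = pd.Series(km.labels_ + 1, index=df.index, name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_, index=range(1, k + 1), columns=df.columns
    )
    return ClusterResult(
        k=k,
        assignments=assignments,
        centroids=centroids,
        wss=float(km.inertia_),
        seed=seed,
        restarts=restarts,
    )


def elbow_curve(
    matrix: SplicingMatrix,
    k_range: range = range(1, 21),
    seed: int = DEFAULT_SEED,
    restarts: int = DEFAULT_RESTARTS,
) -> pd.DataFrame:
    """Within-cluster sum of squares per k, for the elbow diagnostic."""
    df = _as_complete_array(matrix)
    rows = []
    for k in k_range:
        kk = min(k, len(df))
        rows.append({"k": k, "wss": kmeans_cluster(matrix, kk, seed, restarts).wss})
    return pd.DataFrame(rows, columns=["k", "wss"])


def cluster_timepoints(
    centroids: pd.DataFrame,
    method: str = "complete",
    metric: str = "euclidean",
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of timepoint columns from cluster centroids.

    Returns the scipy linkage matrix and the dendrogram leaf order (timepoint
    labels), suitable for ordering heatmap columns.
    """
    cols = list(centroids.columns)
    if len(cols) < 2:
        return np.empty((0, 4)), cols
    Z = linkage(centroids.to_numpy().T, method=method, metric=metric)
    order = [cols[i] for i in leaves_list(Z)]
    return Z, order


def cluster_summary(
    matrix: SplicingMatrix,
    assignments: pd.Series,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-cluster, per-timepoint mean, SD, SE and normal-approximation CI.

    Sample SD (ddof=1; zero for single-row clusters), SE = SD / sqrt(n),
    CI = mean +/- z * SE.
    """
    df = matrix.values.loc[assignments.index]
    z = norm.ppf(0.5 + ci_level / 2)
    rows = []
    for cluster, sub in df.groupby(assignments):
        n = len(sub)
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1) if n > 1 else pd.Series(0.0, index=sub.columns)
        se = sd / np.sqrt(n)
        for tp in df.columns:
            rows.append(
                {
                    "cluster": cluster,
                    "timepoint": tp,
                    "n": n,
                    "mean": mean[tp],
                    "sd": sd[tp],
                    "se": se[tp],
                    "ci_low": mean[tp] - z * se[tp],
                    "ci_high": mean[tp] + z * se[tp],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["cluster", "timepoint", "n", "mean", "sd", "se", "ci_low", "ci_high"],
    )


def expression_foldchange(
    rpkm: pd.DataFrame, gene_ids: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene fold change vs the gene's mean expression across timepoints.

    fc(g, t) = RPKM(g, t) / mean_t RPKM(g, .). All-zero genes have no defined
    fold change and come back as missing rows (logged).
    """
    table = rpkm if gene_ids is None else rpkm.loc[gene_ids]
    means = table.mean(axis=1)
    zero = means == 0
    if zero.any():
        logger.warning(
            "%d gene(s) with all-zero RPKM have undefined fold change", int(zero.sum())
        )
    fc = table.div(means.where(~zero), axis=0)
    return fc


def ordered_matrix(matrix: SplicingMatrix, result: ClusterResult) -> pd.DataFrame:
    """Rows sorted by cluster, columns by the centroid dendrogram leaf order."""
    _, col_order = cluster_timepoints(result.centroids)
    rows = result.assignments.sort_values(kind="stable").index
    return matrix.values.loc[rows, col_order]
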