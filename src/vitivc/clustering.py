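"""Vulnerability clustering of varieties.

Varieties are characterised by their mean embolism thresholds (psi12,
psi50, psi88, MPa).  The traits are Z-scored per column
(``z = (x - mean)/sd``, sample sd), varieties are clustered by
agglomerative Ward linkage on Euclidean distances, the tree is cut at
four clusters, and clusters are ranked by their raw psi50 centroid —
most negative first — into the ordered vulnerability classes
low / low-to-medium / medium-to-high / high.  Each class carries the
midpoint of its quarter of the 0-1 vulnerability scale
(0.125 / 0.375 / 0.625 / 0.875), the weights consumed by the regional
risk index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

TRAIT_COLUMNS = ("psi12", "psi50", "psi88")

CLUSTER_LABELS = ("low", "low-to-medium", "medium-to-high", "high")

#: Midpoint of each quarter of the 0-1 vulnerability scale.
CLUSTER_WEIGHTS = {
    "low": 0.125,
    "low-to-medium": 0.375,
    "medium-to-high": 0.625,
    "high": 0.875,
}


@dataclass
class ClusterAssignment:
    """Ward-clustering result: per-variety labels plus the linkage record."""

    varieties: list[str]
    cluster_id: np.ndarray       # raw fcluster ids, 1..k
    linkage: np.ndarray          # scipy linkage matrix
    k: int


def zscore(matrix: pd.DataFrame, columns=TRAIT_COLUMNS) -> pd.DataFrame:
    """Per-column standardisation: (observed - mean) / sample sd."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 varieties to standardise")
    z = matrix.copy()
    for c in columns:
        sd = matrix[c].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {c!r} has zero variance; Z-score undefined")
        z[c] = (matrix[c] - matrix[c].mean()) / sd
    return z


def ward_cluster(z_matrix: pd.DataFrame, k: int = 4, columns=TRAIT_COLUMNS) -> ClusterAssignment:
    """Agglomerative Ward clustering on the Euclidean distance matrix.

    Uses the Ward.D2 convention (squared-Euclidean Lance-Williams updates
    on Euclidean input distances), the default of modern libraries.  The
    result is deterministic for identical input.
    """
    if len(z_matrix) < k:
        raise ValueError(f"need at least k={k} varieties, got {len(z_matrix)}")
    X = z_matrix[list(columns)].to_numpy(dtype=float)
    link = hierarchy.linkage(pdist(X, metric="euclidean"), method="ward")
    ids = hierarchy.fcluster(link, t=k, criterion="maxclust")
    varieties = (
        z_matrix["variety"].tolist() if "variety" in z_matrix.columns
        else [str(i) for i in z_matrix.index]
    )
    return ClusterAssignment(varieties=varieties, cluster_id=ids, linkage=link, k=k)


def label_clusters(
    assignment: ClusterAssignment,
    raw_matrix: pd.DataFrame,
) -> pd.DataFrame:
    """Order clusters into vulnerability classes and attach weights.

    Clusters are ranked by centroid mean raw psi50 ascending (the most
    negative centroid — the most embolism-resistant group — is 'low'
    vulnerability).  Ties are broken by the psi88, then psi12 centroid.
    Returns a table (variety, cluster, weight) plus centroid columns.
    """
    if assignment.k != len(CLUSTER_LABELS):
        raise ValueError(f"labelling requires exactly {len(CLUSTER_LABELS)} clusters")
    df = raw_matrix.copy()
    df["_cid"] = assignment.cluster_id
    centroids = df.groupby("_cid")[list(TRAIT_COLUMNS)].mean()
    order = centroids.sort_values(["psi50", "psi88", "psi12"]).index
    mapping = {cid: CLUSTER_LABELS[rank] for rank, cid in enumerate(order)}
    out = pd.DataFrame(
        dict(
            variety=assignment.varieties,
            cluster=[mapping[c] for c in assignment.cluster_id],
        )
    )
    out["weight"] = out["cluster"].map(CLUSTER_WEIGHTS)
    return out


def cluster_varieties(variety_means: pd.DataFrame, k: int = 4) -> pd.DataFrame:
    """Z-score, Ward-cluster and label in one step.

    ``variety_means`` needs columns ``variety``, ``psi12``, ``psi50``,
    ``psi88`` (MPa, variety means).  Returns the (variety, cluster, weight)
    assignment table.
    """
    z = zscore(variety_means)
    assignment = ward_cluster(z, k=k)
    return label_clusters(assignment, variety_means)
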