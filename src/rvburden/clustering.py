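"""Ancestry clusters from principal components and Louvain communities.

Cases and controls are matched by genetic ancestry: PCA on a common-variant
dosage matrix captures population structure, Louvain community detection on
a k-nearest-neighbour graph of the first principal components (default 6)
assigns every individual to a cluster, and clusters lacking cases or
controls are dropped before any stratified test. The graph construction is
a symmetric kNN graph (k default 20) with unit edge weights; Louvain node
order is fixed by a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from networkx import Graph
from networkx.algorithms.community import louvain_communities
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

logger = logging.getLogger("rvburden")

__all__ = [
    "ClusterAssignment",
    "project_principal_components",
    "louvain_cluster",
    "filter_clusters",
    "common_variant_mask",
]

DEFAULT_N_COMPONENTS = 6
DEFAULT_K_NEIGHBORS = 20


@dataclass(frozen=True)
class ClusterAssignment:
    """Individual -> cluster labels, with per-cluster phenotype tallies."""

    labels: pd.Series = field(repr=False)  # index sample_id, value cluster id

    def counts(self, phenotypes: pd.Series) -> pd.DataFrame:
        """Per-cluster case/control counts; ``phenotypes`` maps sample_id
        to 'case'/'control'."""
        df = pd.DataFrame({"cluster": self.labels, "phenotype": phenotypes})
        if df["phenotype"].isna().any():
            raise ValueError("phenotype missing for some clustered individuals")
        out = (
            df.groupby("cluster")["phenotype"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=["case", "control"], fill_value=0)
        )
        out.columns.name = None
        return out

    @property
    def cluster_ids(self) -> list:
        return sorted(self.labels.unique())


def common_variant_mask(dosages: np.ndarray, min_maf: float = 0.05) -> np.ndarray:
    """Columns of the dosage matrix with internal minor-allele frequency at
    least ``min_maf`` — the variant set fed to PCA when no predefined list
    is supplied."""
    af = np.asarray(dosages, dtype=float).mean(axis=0) / 2.0
    maf = np.minimum(af, 1 - af)
    return maf >= min_maf


def project_principal_components(
    dosage_matrix: np.ndarray, n_components: int = DEFAULT_N_COMPONENTS
) -> np.ndarray:
    """Top principal-component coordinates of the individuals.

    Columns are mean-centred before the decomposition; components are
    ordered by decreasing explained variance. Requires the matrix to have
    at least ``n_components`` non-degenerate dimensions.
    """
    X = np.asarray(dosage_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("dosage matrix must be 2-dimensional")
    Xc = X - X.mean(axis=0, keepdims=True)
    rank = np.linalg.matrix_rank(Xc) if min(Xc.shape) else 0
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds the matrix rank {rank}"
        )
    # deterministic full SVD; dosage panels here are small enough
    pca = PCA(n_components=n_components, svd_solver="full")
    return pca.fit_transform(Xc)


def louvain_cluster(
    coordinates: np.ndarray,
    sample_ids,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    seed: int = 0,
) -> ClusterAssignment:
    """Louvain communities on a symmetric kNN graph of the PC coordinates.

    Cluster ids are integers ordered by decreasing community size. All
    individuals at identical coordinates collapse to one community (with a
    warning) rather than an error.
    """
    coords = np.asarray(coordinates, dtype=float)
    n = coords.shape[0]
    sample_ids = list(sample_ids)
    if len(sample_ids) != n:
        raise ValueError("sample_ids length must match coordinate rows")
    if n == 1:
        return ClusterAssignment(pd.Series([0], index=sample_ids, name="cluster"))
    if not (1 <= k_neighbors < n):
        raise ValueError("k_neighbors must be >= 1 and < number of individuals")
    if np.allclose(coords, coords[0]):
        logger.warning("all coordinates identical; returning a single cluster")
        return ClusterAssignment(pd.Series(0, index=sample_ids, name="cluster"))
    knn = kneighbors_graph(coords, n_neighbors=k_neighbors, mode="connectivity")
    adj = knn.maximum(knn.T)  # symmetrize, unit weights
    g = Graph(adj)
    comms = louvain_communities(g, seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = np.empty(n, dtype=int)
    for cid, members in enumerate(comms):
        labels[list(members)] = cid
    return ClusterAssignment(pd.Series(labels, index=sample_ids, name="cluster"))


def filter_clusters(
    assignment: ClusterAssignment,
    phenotypes: pd.Series,
    min_cases: int = 1,
    min_controls: int = 1,
) -> ClusterAssignment:
    """Drop clusters with fewer than ``min_cases`` cases or
    ``min_controls`` controls; their individuals leave the analysis."""
    counts = assignment.counts(phenotypes)
    keep = counts.index[
        (counts["case"] >= min_cases) & (counts["control"] >= min_controls)
    ]
    if len(keep) == 0:
        raise ValueError("every cluster fails the case/control minima")
    dropped = counts.index.difference(keep)
    if len(dropped):
        n_excluded = int(assignment.labels.isin(dropped).sum())
        logger.info(
            "dropped %d cluster(s) (%d individuals) failing minima",
            len(dropped), n_excluded,
        )
    kept = assignment.labels[assignment.labels.isin(keep)]
    return ClusterAssignment(kept)
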