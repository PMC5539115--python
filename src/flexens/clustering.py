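"""Final-ensemble extraction by RMSD clustering.

A raw model set is reduced to a final ensemble in three steps: build the
pairwise superposed-RMSD matrix, partition the models with a parameter-free
clustering procedure, and keep the most populous cluster. The clustering is
average-linkage agglomerative with the number of clusters chosen to
maximise the mean silhouette width — a deterministic stand-in for
silhouette-style parameter-free clustering.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .core import ClusterAssignment, CoordinateEnsemble, DistanceMatrix
from .superposition import pairwise_rmsd

__all__ = ["distance_matrix", "cluster", "extract_final_ensemble"]

_ZERO_TOL = 1e-12


def distance_matrix(ens: CoordinateEnsemble) -> DistanceMatrix:
    """Pairwise minimal-RMSD matrix over all models of an ensemble."""
    m = ens.n_models
    if m < 2:
        raise ValueError("need at least 2 models for a distance matrix")
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = pairwise_rmsd(ens.coords[i], ens.coords[j])
    return DistanceMatrix(labels=ens.model_labels, d=d)


def cluster(dm: DistanceMatrix, k_max: int = 10, seed: int | None = None) -> ClusterAssignment:
    """Partition models by average-linkage clustering at the silhouette-optimal k.

    k is searched over [2, min(k_max, M-1)] and the partition with the
    highest mean silhouette width (computed from the RMSD matrix) wins.
    A single cluster (quality -1) is returned only when M < 3 or when all
    pairwise distances vanish. Deterministic for a given matrix; ``seed``
    is accepted for interface symmetry but unused.
    """
    m = dm.n
    if m < 2:
        raise ValueError("need at least 2 models")
    if m < 3 or np.all(dm.d <= _ZERO_TOL):
        return ClusterAssignment(
            labels=dm.labels, cluster_ids=(0,) * m, k=1, quality=-1.0
        )

    z = linkage(squareform(dm.d, checks=False), method="average")
    best: tuple[float, int, np.ndarray] | None = None
    for k in range(2, min(k_max, m - 1) + 1):
        ids = fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(ids)) < 2:
            continue
        score = float(silhouette_score(dm.d, ids, metric="precomputed"))
        if best is None or score > best[0]:
            best = (score, k, ids)
    if best is None:  # linkage could not split (all distances tied at zero)
        return ClusterAssignment(
            labels=dm.labels, cluster_ids=(0,) * m, k=1, quality=-1.0
        )
    quality, _, ids = best
    # renumber clusters 0..k-1 in order of first appearance
    remap: dict[int, int] = {}
    cluster_ids = []
    for c in ids:
        if c not in remap:
            remap[c] = len(remap)
        cluster_ids.append(remap[c])
    return ClusterAssignment(
        labels=dm.labels,
        cluster_ids=tuple(cluster_ids),
        k=len(remap),
        quality=quality,
    )


def extract_final_ensemble(
    ens: CoordinateEnsemble, ca: ClusterAssignment, dm: DistanceMatrix | None = None
) -> CoordinateEnsemble:
    """Sub-ensemble of the most populous cluster.

    Size ties are broken towards the cluster with the smaller mean
    intra-cluster distance (recomputed from ``dm``, or from the coordinates
    when no matrix is supplied), then towards the lowest cluster id.
    """
    if ca.labels != ens.model_labels:
        raise ValueError("cluster assignment labels do not match ensemble models")

    sizes = {c: len(ca.members(c)) for c in range(ca.k)}
    max_size = max(sizes.values())
    candidates = [c for c, s in sizes.items() if s == max_size]
    if len(candidates) > 1:
        if dm is None:
            dm = distance_matrix(ens)

        def intra_mean(c: int) -> float:
            idx = ca.members(c)
            if len(idx) < 2:
                return 0.0
            sub = dm.d[np.ix_(idx, idx)]
            return float(sub[np.triu_indices(len(idx), k=1)].mean())

        candidates.sort(key=lambda c: (intra_mean(c), c))
    winner = candidates[0]
    return ens.subset_models(ca.members(winner))
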