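"""Jarvis-Patrick shared-nearest-neighbor clustering of conformational
ensembles over pairwise superposed RMSD.

A structure joins a cluster when it is among the K nearest neighbours
(default 10, RMSD metric) of another member, the relation is mutual, and
the two share at least ``min_shared`` (default 3) common neighbours.
Clusters are the connected components of that graph; frames with no edge
are singletons.  Each cluster's central (representative) structure is the
member with the smallest average RMSD to all other members, and the
cluster with the most members is the most populated one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import superposed_rmsd
from .trajectory_io import Trajectory, select

__all__ = [
    "ClusterResult",
    "pairwise_rmsd",
    "jarvis_patrick",
    "central_structures",
    "census",
]


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-frame cluster id (0-based, arbitrary order)
    sizes: np.ndarray  # per-cluster member counts
    central: np.ndarray  # per-cluster representative frame index
    most_populated: int  # cluster id of maximal size

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def pairwise_rmsd(traj_or_coords, selection: str | np.ndarray | None = "backbone") -> np.ndarray:
    """Symmetric matrix of superposed RMSD between all frame pairs."""
    if isinstance(traj_or_coords, Trajectory):
        if selection is None:
            sel_idx = np.arange(traj_or_coords.n_atoms)
        elif isinstance(selection, str):
            sel_idx = select(traj_or_coords, selection)
            if len(sel_idx) < 3:
                sel_idx = np.arange(traj_or_coords.n_atoms)
        else:
            sel_idx = np.asarray(selection)
        coords = traj_or_coords.coordinates()[:, sel_idx, :]
    else:
        coords = np.asarray(traj_or_coords)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least two frames")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = superposed_rmsd(coords[i], coords[j])
    return d


def _neighbor_lists(d: np.ndarray, k: int) -> np.ndarray:
    """K nearest neighbours per row, self excluded, distance ties broken by
    lower index (lexicographic argsort on (distance, index))."""
    n = d.shape[0]
    nn = np.empty((n, k), dtype=int)
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, d[i]))
        order = order[order != i]
        nn[i] = order[:k]
    return nn


def jarvis_patrick(d: np.ndarray, k: int = 10, min_shared: int = 3) -> ClusterResult:
    """Cluster a distance matrix by the shared-nearest-neighbour rule.

    Edge (i, j) iff i and j are mutual K-nearest neighbours and their
    neighbour lists share at least ``min_shared`` members (not counting i
    or j themselves); clusters are connected components.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two structures")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of structures {n}")
    nn = _neighbor_lists(d, k)
    nn_sets = [set(row) for row in nn]
    rows, cols = [], []
    for i in range(n):
        for j in nn_sets[i]:
            if j <= i:
                continue
            if i not in nn_sets[j]:
                continue
            shared = (nn_sets[i] & nn_sets[j]) - {i, j}
            if len(shared) >= min_shared:
                rows.append(i)
                cols.append(j)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    central = central_structures(d, labels, n_comp)
    most = int(np.argmax(sizes))  # ties: lowest label
    return ClusterResult(labels=labels, sizes=sizes, central=central, most_populated=most)


def central_structures(d: np.ndarray, labels: np.ndarray, n_clusters: int | None = None) -> np.ndarray:
    """Per-cluster frame minimizing the mean distance to the other members
    (ties broken by lowest frame index; singletons are their own centre)."""
    if n_clusters is None:
        n_clusters = int(labels.max()) + 1
    central = np.empty(n_clusters, dtype=int)
    for c in range(n_clusters):
        members = np.flatnonzero(labels == c)
        if len(members) == 1:
            central[c] = members[0]
            continue
        sub = d[np.ix_(members, members)]
        mean_d = sub.sum(axis=1) / (len(members) - 1)
        central[c] = members[int(np.argmin(mean_d))]
    return central


def census(result: ClusterResult):
    """Cluster size table sorted descending (ties by cluster id), with the
    most-populated cluster flagged.  Returns a list of
    ``(cluster_id, size, central_frame, is_most_populated)`` rows."""
    order = sorted(range(result.n_clusters), key=lambda c: (-result.sizes[c], c))
    return [
        (c, int(result.sizes[c]), int(result.central[c]), c == result.most_populated)
        for c in order
    ]
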