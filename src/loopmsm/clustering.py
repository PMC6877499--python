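"""Average-linkage conformational clustering with a distance cut-off.

Agglomerative merging by smallest average inter-cluster distance, stopped
when the minimum average linkage exceeds the cut-off epsilon; clusters are
renumbered 1..k by descending population.  The cut-off is a required,
per-system parameter — loop flexibility differs between systems and no
silent auto-tuning is done (a helper reports the cluster-count-vs-epsilon
curve instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .canonical import dihedral_distance
from .geometry import BackboneChain, kabsch_rmsd


@dataclass
class ClusterResult:
    labels: np.ndarray               # per frame, 1-based, by descending size
    representatives: np.ndarray      # per cluster (frame index), index = label-1
    epsilon: float
    traj_labels: list[np.ndarray] | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def pairwise_distance_matrix(frames, metric: str = "kabsch-rmsd",
                             include=frozenset({"phi", "psi"})) -> np.ndarray:
    """Symmetric all-vs-all distance matrix.

    metric = "kabsch-rmsd" expects BackboneChains (or (n,3) atom arrays);
    metric = "dihedral-distance" expects per-frame torsion vectors of shape
    (L, 3) in degrees.
    """
    n = len(frames)
    if n < 2:
        raise ValueError("need >= 2 frames")
    D = np.zeros((n, n))
    if metric == "kabsch-rmsd":
        if not isinstance(frames[0], (BackboneChain, np.ndarray)):
            raise ValueError("kabsch-rmsd metric needs coordinate frames")
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = kabsch_rmsd(frames[i], frames[j])
    elif metric == "dihedral-distance":
        try:
            arr = np.asarray(frames, dtype=float)
        except (TypeError, ValueError) as e:
            raise ValueError(
                "dihedral-distance metric needs torsion frames, not "
                f"{type(frames[0]).__name__}") from e
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError("dihedral-distance metric needs (n, L, 3) torsion frames")
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = dihedral_distance(arr[i], arr[j],
                                                      include=include)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return D


def average_linkage_cluster(d: np.ndarray, epsilon: float,
                            traj_lengths=None) -> ClusterResult:
    """Average-linkage clustering of a distance matrix with cut-off epsilon.

    Merging stops when the minimum average inter-cluster distance exceeds
    epsilon (average linkage is monotone, so this equals cutting the
    dendrogram at height epsilon).
    """
    d = np.asarray(d, dtype=float)
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if n == 1:
        raw = np.array([1])
    else:
        Z = linkage(squareform(d, checks=False), method="average")
        raw = fcluster(Z, t=epsilon, criterion="distance")
    labels = _renumber_by_population(raw)
    reps = pick_representatives_from_labels(labels, d)
    traj_labels = None
    if traj_lengths is not None:
        traj_labels = []
        ofs = 0
        for ln in traj_lengths:
            traj_labels.append(labels[ofs:ofs + ln])
            ofs += ln
    return ClusterResult(labels=labels, representatives=reps, epsilon=float(epsilon),
                         traj_labels=traj_labels)


def _renumber_by_population(raw: np.ndarray) -> np.ndarray:
    """Renumber labels 1..k by descending cluster size (ties: lower first
    frame index first)."""
    ids, first = np.unique(raw, return_index=True)
    sizes = np.array([(raw == i).sum() for i in ids])
    order = sorted(range(len(ids)), key=lambda t: (-sizes[t], first[t]))
    mapping = {ids[t]: rank + 1 for rank, t in enumerate(order)}
    return np.array([mapping[v] for v in raw], dtype=np.int64)


def pick_representatives_from_labels(labels: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Per cluster, the member minimising the sum of distances to its
    co-members; exact ties go to the lowest frame index."""
    k = int(labels.max())
    reps = np.empty(k, dtype=np.int64)
    for c in range(1, k + 1):
        members = np.nonzero(labels == c)[0]
        sums = d[np.ix_(members, members)].sum(axis=1)
        reps[c - 1] = members[int(np.argmin(sums))]   # argmin takes first on ties
    return reps


def pick_representatives(result: ClusterResult, d: np.ndarray) -> np.ndarray:
    return pick_representatives_from_labels(result.labels, np.asarray(d, dtype=float))


def transition_series(label_seqs):
    """Count cluster-label changes within each trajectory.

    Returns (total transition count, per-trajectory arrays of change
    positions — the frame index at which the new label first holds).
    Boundaries between trajectories are never counted.
    """
    seqs = [np.asarray(s) for s in label_seqs]
    if not seqs or any(len(s) == 0 for s in seqs):
        raise ValueError("labels must be non-empty")
    positions = []
    total = 0
    for s in seqs:
        pos = np.nonzero(s[1:] != s[:-1])[0] + 1
        positions.append(pos)
        total += len(pos)
    return total, positions


def cluster_count_curve(d: np.ndarray, epsilons) -> pd.DataFrame:
    """Cluster count as a function of the cut-off (helper for choosing
    epsilon per system)."""
    rows = [{"epsilon": float(e),
             "n_clusters": average_linkage_cluster(d, float(e)).n_clusters}
            for e in epsilons]
    return pd.DataFrame(rows)
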