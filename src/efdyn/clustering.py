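"""GROMOS (Daura) conformational clustering of trajectory frames.

Frames are compared by pairwise Cα RMSD after optimal superposition;
the greedy rule repeatedly takes the frame with the most neighbours
within the cutoff as a cluster representative, removes it and its
neighbours, and recurses on the remainder.  Cluster population weights
feed the Brownian-dynamics rate averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .model_io import Structure, Trajectory, select

__all__ = [
    "ClusterSet",
    "pairwise_rmsd",
    "gromos_cluster",
    "representatives",
]


@dataclass
class Cluster:
    members: list[int]  # frame indices
    representative: int
    weight: float


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    cutoff: float

    def __post_init__(self) -> None:
        seen: set[int] = set()
        total = 0
        for c in self.clusters:
            if seen & set(c.members):
                raise ValueError("clusters must be disjoint")
            seen |= set(c.members)
            total += len(c.members)
        if abs(sum(c.weight for c in self.clusters) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        sizes = [len(c.members) for c in self.clusters]
        if any(sizes[i] < sizes[i + 1] for i in range(len(sizes) - 1)):
            raise ValueError("cluster sizes must be non-increasing")

    @property
    def n_frames(self) -> int:
        return sum(len(c.members) for c in self.clusters)

    def coverage(self, k: int) -> float:
        """Population fraction of the k largest clusters."""
        return sum(c.weight for c in self.clusters[:k])

    def assignments(self) -> dict[int, int]:
        """frame index -> cluster index."""
        return {
            f: i for i, c in enumerate(self.clusters) for f in c.members
        }

    def to_table(self) -> str:
        lines = ["frame\tcluster"]
        for f, c in sorted(self.assignments().items()):
            lines.append(f"{f}\t{c}")
        return "\n".join(lines) + "\n"


def pairwise_rmsd(
    traj: Trajectory, selection: str = "name CA", stride: int = 1
) -> np.ndarray:
    """Symmetric matrix of pairwise Cα RMSDs, each pair optimally superposed.

    ``stride`` subsamples frames (the study stored snapshots every 6 ps).
    Because every pair is fitted independently, mild triangle-inequality
    violations are possible; the matrix is a dissimilarity, not a metric.
    """
    sel = np.array(select(traj, selection))
    if sel.size == 0:
        raise ValueError("empty selection for pairwise RMSD")
    frames = traj.frames[::stride, sel, :]
    n = frames.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames after stride")
    centred = frames - frames.mean(axis=1, keepdims=True)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rot, rssd = Rotation.align_vectors(centred[i], centred[j])
            out[i, j] = out[j, i] = rssd / np.sqrt(sel.size)
    return out


def gromos_cluster(rmsd_matrix: np.ndarray, cutoff: float) -> ClusterSet:
    """Greedy neighbour-count clustering of a pairwise RMSD matrix.

    At each round the frame with the most neighbours within ``cutoff``
    (the frame itself counts) becomes a representative; ties go to the
    lowest frame index.  Sizes are non-increasing by construction, so the
    cluster list is emitted in extraction order.
    """
    m = np.asarray(rmsd_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] == 0:
        raise ValueError("rmsd_matrix must be a non-empty square matrix")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = m.shape[0]
    within = m <= cutoff
    np.fill_diagonal(within, True)
    alive = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while alive.any():
        counts = np.where(alive, (within & alive[None, :]).sum(axis=1), -1)
        rep = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = sorted(np.nonzero(within[rep] & alive)[0].tolist())
        clusters.append(Cluster(members, rep, len(members) / n))
        alive[members] = False
    return ClusterSet(clusters, cutoff)


def representatives(
    cluster_set: ClusterSet, traj: Trajectory, stride: int = 1
) -> list[tuple[Structure, float]]:
    """Representative Structure and population weight per cluster.

    ``stride`` must match the stride used for the RMSD matrix so cluster
    frame indices map back to trajectory frames.
    """
    out = []
    for c in cluster_set.clusters:
        frame = c.representative * stride
        s = traj.frame_structure(frame)
        out.append((s, c.weight))
    return out
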