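"""Single-linkage conformational clustering under backbone RMSD.

Frames (optionally strided, default every 10th) are compared pairwise by
superposed backbone RMSD; two frames share a cluster when they are joined
by a chain of pairwise distances each below the cutoff (default 0.35 nm).
That is exactly the partition a single-linkage dendrogram cut produces, and
is computed here as connected components of the threshold graph, which is
O(n^2) and simple at the few-thousand-frame scale. Clusters are ordered by
size (ties: smallest member frame), and each cluster reports a
representative frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import kabsch_superpose
from .topology import Selection
from .trajectory import Trajectory

__all__ = ["RMSD_CUTOFF", "DEFAULT_STRIDE", "ClusterAssignment",
           "pairwise_rmsd_matrix", "single_linkage"]

RMSD_CUTOFF = 0.35   # nm (3.5 Angstrom)
DEFAULT_STRIDE = 10


@dataclass
class ClusterAssignment:
    """Partition of (strided) frames into RMSD clusters."""

    frame_indices: np.ndarray       # original frame numbers analysed
    labels: np.ndarray              # cluster label per analysed frame, 0 = largest
    sizes: list[int]                # per cluster, descending
    representatives: list[int]      # original frame number per cluster
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": self.frame_indices, "cluster": self.labels})

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster": np.arange(self.n_clusters),
            "size": self.sizes,
            "representative_frame": self.representatives,
        })


def pairwise_rmsd_matrix(traj: Trajectory, selection=None,
                         stride: int = DEFAULT_STRIDE) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric matrix of superposed RMSDs between strided frames.

    Returns ``(matrix, frame_indices)``; entry (i, j) is the Kabsch-minimal
    backbone RMSD between analysed frames i and j.
    """
    topo = traj.topology
    if selection is None:
        selection = Selection(molecule_kind="protein", role="backbone")
    idx = selection.resolve(topo) if isinstance(selection, Selection) \
        else np.asarray(selection, dtype=int)
    if len(idx) == 0:
        raise ValueError("empty selection")
    if stride >= traj.n_frames:
        raise ValueError(f"stride {stride} >= frame count {traj.n_frames}")
    frames = np.arange(0, traj.n_frames, stride)
    if len(frames) < 2:
        raise ValueError("need at least 2 strided frames")
    w = topo.mass[idx]
    coords = [traj.coordinates[f][idx] for f in frames]
    n = len(frames)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, mat[i, j] = kabsch_superpose(coords[i], coords[j], w)
            mat[j, i] = mat[i, j]
    return mat, frames


def single_linkage(matrix: np.ndarray, cutoff: float = RMSD_CUTOFF,
                   frame_indices: np.ndarray | None = None,
                   representative: str = "min_mean_rmsd") -> ClusterAssignment:
    """Single-linkage clusters as threshold-graph connected components.

    Frames i and j share a cluster iff a chain of pairwise distances each
    strictly below ``cutoff`` connects them. Representatives are the member
    with minimal mean RMSD to its cluster (``min_mean_rmsd``) or the member
    with the most neighbors within the cutoff (``max_neighbors``); ties go
    to the smaller frame index.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = matrix.shape[0]
    if frame_indices is None:
        frame_indices = np.arange(n)
    adj = csr_matrix((matrix < cutoff).astype(np.int8))
    n_comp, comp = connected_components(adj, directed=False)

    members = [np.flatnonzero(comp == c) for c in range(n_comp)]
    order = sorted(range(n_comp), key=lambda c: (-len(members[c]), members[c].min()))
    labels = np.empty(n, dtype=int)
    sizes, reps = [], []
    for new_label, c in enumerate(order):
        mem = members[c]
        labels[mem] = new_label
        sizes.append(len(mem))
        sub = matrix[np.ix_(mem, mem)]
        if representative == "min_mean_rmsd":
            score = sub.mean(axis=1)
            best = mem[int(np.argmin(score))]
        elif representative == "max_neighbors":
            score = (sub < cutoff).sum(axis=1)
            best = mem[int(np.argmax(score))]
        else:
            raise ValueError(f"unknown representative rule {representative!r}")
        reps.append(int(frame_indices[best]))
    return ClusterAssignment(np.asarray(frame_indices), labels, sizes, reps, cutoff)
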