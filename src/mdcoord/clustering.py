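"""GROMOS-style conformational clustering.

Greedy neighbour-count clustering on the all-pairs RMSD matrix: the frame
with the most neighbours within the cutoff seeds a cluster together with
all those neighbours, the cluster is removed from the pool, and the
procedure repeats until the pool is empty.  Clusters are disjoint and
exhaustive, and the central structure of each cluster is its seed frame.

The default presets mirror a rotamer-region analysis: selection = residues
124-131 of the beta chain, cutoffs 2.0 Å and 3.0 Å (0.2 / 0.3 nm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DomainDefinition, Selection, Trajectory, kabsch, rmsd

__all__ = ["ClusterResult", "pairwise_rmsd_matrix", "gromos_cluster",
           "CUTOFF_TIGHT_A", "CUTOFF_LOOSE_A", "w129_region"]

CUTOFF_TIGHT_A = 2.0    # 0.2 nm
CUTOFF_LOOSE_A = 3.0    # 0.3 nm


def w129_region(chain: str = "B") -> DomainDefinition:
    """The alpha1-helix rotamer region around W129 (residues 124-131)."""
    return DomainDefinition("w129-region", chain, ((124, 131),))


@dataclass
class ClusterResult:
    """A disjoint, exhaustive partition of frames into RMSD clusters."""

    frame_cluster: np.ndarray        # (F,) cluster id per frame, 0-based
    centers: list[int]               # central frame index per cluster
    sizes: list[int]
    populations: list[float]         # % of frames
    cutoff_nm: float

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(self.frame_cluster.size),
                             "cluster": self.frame_cluster})

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"cluster": np.arange(self.n_clusters),
                             "center_frame": self.centers,
                             "size": self.sizes,
                             "population_pct": self.populations})


def pairwise_rmsd_matrix(traj: Trajectory, selection: Selection,
                         fit_selection: Selection | None = None,
                         max_frames: int = 2000,
                         stride: int | None = None,
                         superpose: bool = True) -> np.ndarray:
    """All-pairs RMSD (Å) with per-pair superposition on ``fit_selection``
    (default: the analysis selection itself; ``superpose=False`` compares
    raw coordinates, e.g. for trajectories already fitted globally).

    The matrix is O(F^2); beyond ``max_frames`` frames a stride must be
    given explicitly.
    """
    if stride is not None:
        frames = traj.frames[::stride]
    else:
        frames = traj.frames
    F = frames.shape[0]
    if F == 0:
        raise ValueError("empty trajectory")
    if F > max_frames:
        raise ValueError(f"{F} frames exceed the all-pairs cap "
                         f"({max_frames}); pass a stride")
    fit = fit_selection if fit_selection is not None else selection
    fi = fit.array
    si = selection.array
    M = np.zeros((F, F))
    for i in range(F):
        for j in range(i + 1, F):
            if superpose:
                R, t = kabsch(frames[j, fi], frames[i, fi])
                moved = frames[j, si] @ R.T + t
            else:
                moved = frames[j, si]
            M[i, j] = M[j, i] = float(np.sqrt(np.mean(
                np.sum((moved - frames[i, si]) ** 2, axis=1))))
    return M


def gromos_cluster(traj: Trajectory, selection: Selection,
                   cutoff: float = CUTOFF_TIGHT_A,
                   fit_selection: Selection | None = None,
                   stride: int | None = None,
                   max_frames: int = 2000,
                   superpose: bool = True) -> ClusterResult:
    """Greedy neighbour-count clustering at an RMSD ``cutoff`` (Å).

    Ties in the neighbour count are broken by the lowest frame index, so
    the partition is deterministic.  Every member lies within the cutoff of
    its cluster's centre at assignment time.
    """
    M = pairwise_rmsd_matrix(traj, selection, fit_selection,
                             max_frames=max_frames, stride=stride,
                             superpose=superpose)
    F = M.shape[0]
    neighbors = M <= cutoff                  # includes self on the diagonal
    remaining = np.ones(F, dtype=bool)
    assignment = np.full(F, -1, dtype=int)
    centers: list[int] = []
    sizes: list[int] = []
    cid = 0
    while remaining.any():
        counts = (neighbors & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))      # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbors[center] & remaining)
        assignment[members] = cid
        centers.append(center)
        sizes.append(int(members.size))
        remaining[members] = False
        cid += 1
    populations = [100.0 * s / F for s in sizes]
    return ClusterResult(frame_cluster=assignment, centers=centers,
                         sizes=sizes, populations=populations,
                         cutoff_nm=cutoff / 10.0)
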