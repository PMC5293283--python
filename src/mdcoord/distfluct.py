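"""Distance-fluctuation coordination matrices and per-residue RMSF.

The distance fluctuation between residues i and j is the time-averaged
mean-square fluctuation of their Calpha-Calpha distance,

    DF_ij = < (r_ij - <r_ij>)^2 >,

where <.> is the average over trajectory frames (population convention).
Low DF marks pairs that move as a mechanically coordinated unit; high DF
marks flexible inter-residue geometry.  Being built on internal distances,
DF is exactly invariant under per-frame global rotations/translations and
vanishes on any rigid subset.

Multi-replica results are the arithmetic mean of per-replica matrices, so
static offsets between independently equilibrated replicas cannot inflate
the fluctuation estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import Selection, StructureModel, Trajectory

__all__ = ["DFMatrix", "RMSFProfile", "df_matrix", "rmsf_profile"]


@dataclass
class DFMatrix:
    """Symmetric per-pair mean-square distance-fluctuation matrix (Å²)."""

    labels: list[str]
    matrix: np.ndarray           # (n, n) Å², diagonal 0
    n_frames: int
    replicas: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        return pd.DataFrame({
            "i": [self.labels[a] for a in iu[0]],
            "j": [self.labels[b] for b in iu[1]],
            "df": self.matrix[iu]})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation (Å) with replica spread."""

    labels: list[str]
    mean: np.ndarray             # (n,) Å, mean over replicas
    std: np.ndarray              # (n,) Å, std across replicas
    per_replica: np.ndarray      # (R, n) Å

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels, "rmsf": self.mean,
                             "std": self.std})


def _single_replica_df(frames: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Streaming two-moment accumulation of pairwise-distance variance."""
    n = idx.size
    s1 = np.zeros(n * (n - 1) // 2)
    s2 = np.zeros_like(s1)
    F = frames.shape[0]
    for f in range(F):
        d = pdist(frames[f, idx])
        s1 += d
        s2 += d * d
    mean = s1 / F
    var = s2 / F - mean * mean          # population variance over frames
    return squareform(np.clip(var, 0.0, None))


def df_matrix(trajs: list[Trajectory] | Trajectory,
              selection: Selection) -> DFMatrix:
    """Distance-fluctuation matrix over one or more replicas.

    Each replica needs at least two frames; replica matrices are averaged.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs:
        raise ValueError("no trajectories given")
    idx = selection.array
    mats, replicas, total_frames = [], [], 0
    for traj in trajs:
        if traj.n_frames < 2:
            raise ValueError(
                f"replica {traj.replica}: need >= 2 frames for fluctuations")
        mats.append(_single_replica_df(traj.frames, idx))
        replicas.append(traj.replica)
        total_frames += traj.n_frames
    labels = trajs[0].reference.atom_labels(idx)
    return DFMatrix(labels=labels, matrix=np.mean(mats, axis=0),
                    n_frames=total_frames, replicas=replicas)


def rmsf_profile(trajs: list[Trajectory] | Trajectory,
                 selection: Selection,
                 reference: StructureModel | None = None) -> RMSFProfile:
    """Per-atom RMSF about the time-mean position, averaged over replicas.

    Trajectories are expected to be superposed on ``reference`` beforehand;
    if a replica's mean deviates grossly from the reference over the
    selection a warning is emitted (symptom of an unfitted trajectory).
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs:
        raise ValueError("no trajectories given")
    idx = selection.array
    per_rep = []
    for traj in trajs:
        x = traj.frames[:, idx, :]
        mean = x.mean(axis=0)
        if reference is not None:
            drift = np.sqrt(np.mean(np.sum(
                (mean - reference.coords[idx]) ** 2, axis=1)))
            if drift > 10.0:
                import warnings
                warnings.warn(
                    f"replica {traj.replica}: mean structure deviates "
                    f"{drift:.1f} Å from reference; trajectory may not be "
                    f"superposed", stacklevel=2)
        per_rep.append(np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0)))
    per_rep = np.asarray(per_rep)
    labels = trajs[0].reference.atom_labels(idx)
    return RMSFProfile(labels=labels, mean=per_rep.mean(axis=0),
                       std=per_rep.std(axis=0), per_replica=per_rep)
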