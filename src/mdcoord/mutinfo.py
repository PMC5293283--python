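"""Generalized correlation from k-nearest-neighbour mutual information.

Pearson-type correlations of atomic fluctuations miss couplings between
motions that are orthogonal or nonlinearly related.  The generalized
correlation coefficient maps the mutual information I between two atoms'
3-D displacement series onto a correlation-like scale,

    r_MI = sqrt(1 - exp(-2 I / d)),   d = 3,

which equals |rho| for jointly Gaussian displacements and is insensitive to
the relative orientation of the motions.  I is estimated with the
Kraskov-Stoegbauer-Grassberger (KSG) k-nearest-neighbour estimator
(variant 1, Chebyshev norm, natural log), with k = 6 neighbours by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

from .core import Selection, Trajectory

__all__ = ["LMIMatrix", "knn_mutual_information", "generalized_correlation",
           "generalized_correlation_matrix"]


@dataclass
class LMIMatrix:
    """Symmetric matrix of generalized correlation coefficients in [0, 1]."""

    labels: list[str]
    matrix: np.ndarray
    k: int
    dimensionality: int
    replicas: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        return pd.DataFrame({
            "i": [self.labels[a] for a in iu[0]],
            "j": [self.labels[b] for b in iu[1]],
            "r_mi": self.matrix[iu]})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _as_2d(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    return a[:, None] if a.ndim == 1 else a


def knn_mutual_information(x: np.ndarray, y: np.ndarray, k: int = 6,
                           on_duplicates: str = "jitter") -> float:
    """KSG variant-1 mutual information estimate in nats.

    Chebyshev (max-norm) distances in the joint space define the k-th
    neighbour radius eps_i; marginal neighbour counts use the strict
    inequality ``< eps_i``.  Exactly duplicated points collapse eps to zero;
    per ``on_duplicates`` they are either broken by a tiny deterministic
    jitter (1e-10 of the coordinate scale) or raised as an error.  Small
    negative estimates are clamped to 0.
    """
    X, Y = _as_2d(x), _as_2d(y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("x and y must have the same number of samples")
    n = X.shape[0]
    if n <= k + 1:
        raise ValueError(f"need more than k+1={k + 1} samples, got {n}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("samples must be finite")
    joint = np.hstack([X, Y])
    tree = cKDTree(joint)
    eps = tree.query(joint, k=k + 1, p=np.inf)[0][:, -1]
    if np.any(eps == 0.0):
        if on_duplicates == "error":
            raise ValueError("duplicate samples give a zero kth-neighbour "
                             "distance; set on_duplicates='jitter'")
        scale = max(np.abs(joint).max(), 1.0)
        rng = np.random.default_rng(n)        # deterministic tie-break noise
        joint = joint + rng.normal(0.0, 1e-10 * scale, size=joint.shape)
        X = joint[:, :X.shape[1]]
        Y = joint[:, X.shape[1]:]
        eps = cKDTree(joint).query(joint, k=k + 1, p=np.inf)[0][:, -1]
    # strict < eps: shrink the radius by one part in 1e10
    r = eps * (1.0 - 1e-10)
    nx = cKDTree(X).query_ball_point(X, r, p=np.inf, return_length=True) - 1
    ny = cKDTree(Y).query_ball_point(Y, r, p=np.inf, return_length=True) - 1
    mi = (digamma(k) + digamma(n)
          - float(np.mean(digamma(nx + 1) + digamma(ny + 1))))
    return max(0.0, mi)


def generalized_correlation(x: np.ndarray, y: np.ndarray, k: int = 6,
                            d: int | None = None) -> float:
    """r_MI = sqrt(1 - exp(-2 I / d)) in [0, 1]; d defaults to the sample
    dimensionality.

    Identical series carry unbounded mutual information, but any finite-
    sample estimate saturates near digamma(n) - digamma(k); that degenerate
    case is returned as exactly 1.
    """
    X, Y = _as_2d(x), _as_2d(y)
    if X.shape == Y.shape and np.array_equal(X, Y):
        return 1.0
    if d is None:
        d = X.shape[1]
    mi = knn_mutual_information(X, Y, k=k)
    return float(min(1.0, np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * mi / d)))))


def _auto_stride(n_frames: int, max_frames: int) -> int:
    return max(1, int(np.ceil(n_frames / max_frames)))


def generalized_correlation_matrix(trajs: list[Trajectory] | Trajectory,
                                   selection: Selection, k: int = 6,
                                   stride: int | None = None,
                                   max_frames: int = 2000) -> LMIMatrix:
    """Generalized correlation matrix over atom pairs of ``selection``.

    Per replica, each atom's 3-D displacement series about its time mean
    feeds the KSG estimator pairwise; replica matrices are averaged.
    Frames must be superposed beforehand so displacements, not rigid-body
    motion, are correlated.  ``stride`` subsamples frames (default: the
    smallest stride keeping at most ``max_frames`` frames; the KSG cost is
    O(pairs * F log F)).
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs:
        raise ValueError("no trajectories given")
    idx = selection.array
    n = idx.size
    mats, replicas = [], []
    for traj in trajs:
        s = stride if stride is not None else _auto_stride(traj.n_frames,
                                                           max_frames)
        X = traj.frames[::s, idx, :]
        disp = X - X.mean(axis=0)
        M = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                M[i, j] = M[j, i] = generalized_correlation(
                    disp[:, i, :], disp[:, j, :], k=k, d=3)
        mats.append(M)
        replicas.append(traj.replica)
    labels = trajs[0].reference.atom_labels(idx)
    return LMIMatrix(labels=labels, matrix=np.mean(mats, axis=0), k=k,
                     dimensionality=3, replicas=replicas)
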