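"""Essential dynamics: covariance PCA of Calpha coordinates with
projections, variance fractions and sampling diagnostics.

The covariance of the 3N Cartesian Calpha coordinates (mass-unweighted,
frames pooled over replicas after superposition to a common reference) is
diagonalized; the leading eigenvectors are the "essential" collective modes
that carry most of the positional fluctuation variance.  Sampling quality
is diagnosed by the split-half essential-subspace overlap (root-mean-square
inner product) and by the cosine content of mode projections: projections
of an unconverged random-diffusion-like trajectory resemble cosines with
the mode rank's half-period count, so a cosine content near 1 flags poor
sampling while values near 0 are consistent with converged fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Selection, StructureModel, Trajectory

__all__ = ["EDResult", "SamplingDiagnostics", "fit_pca", "project_trajectory",
           "cosine_content", "subspace_overlap", "split_half_diagnostics"]


@dataclass
class EDResult:
    """Eigen-decomposition of the pooled Calpha coordinate covariance."""

    mean: np.ndarray            # (3n,) mean structure over pooled frames, Å
    eigenvalues: np.ndarray     # (3n,) Å², descending, clamped at 0
    eigenvectors: np.ndarray    # (3n, 3n) orthonormal columns
    selection: Selection
    n_frames: int

    @property
    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues

    @property
    def trace(self) -> float:
        return float(self.eigenvalues.sum())


@dataclass
class SamplingDiagnostics:
    """Split-half essential-subspace overlap and per-mode cosine content."""

    split_half_overlap: float
    cosine_contents: np.ndarray


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign: the largest-magnitude component of each
    eigenvector is made positive (first such index on ties)."""
    out = vectors.copy()
    for k in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, k])))
        if out[i, k] < 0:
            out[:, k] = -out[:, k]
    return out


def _pooled_coords(trajs: list[Trajectory] | Trajectory,
                   selection: Selection) -> np.ndarray:
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    idx = selection.array
    X = np.concatenate([t.frames[:, idx, :] for t in trajs], axis=0)
    return X.reshape(X.shape[0], -1)          # (F, 3n)


def fit_pca(trajs: list[Trajectory] | Trajectory,
            selection: Selection,
            reference: StructureModel | None = None) -> EDResult:
    """Covariance PCA over pooled replica frames.

    Frames must already be superposed to the common reference over the
    selection (``reference`` is accepted for interface symmetry and future
    drift checks).  Modes are sorted by descending eigenvalue with a
    deterministic sign convention; eigenvalues are clamped at zero.
    """
    X = _pooled_coords(trajs, selection)
    if X.shape[0] <= 1:
        raise ValueError("PCA needs more than one frame")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / X.shape[0]            # population covariance
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _fix_signs(evecs[:, order])
    return EDResult(mean=mean, eigenvalues=evals, eigenvectors=evecs,
                    selection=selection, n_frames=X.shape[0])


def project_trajectory(traj: Trajectory | list[Trajectory], ed: EDResult,
                       modes: list[int] | None = None) -> np.ndarray:
    """Per-frame projections onto the requested modes (0-based ranks).

    Projection of frame x on mode k is ``(x - mean) . v_k``; for the
    ensemble the PCA was fitted on, the projection variance on mode k
    equals eigenvalue k.
    """
    X = _pooled_coords(traj, ed.selection)
    if modes is None:
        modes = [0, 1]
    for m in modes:
        if not (0 <= m < ed.eigenvectors.shape[1]):
            raise IndexError(f"mode index {m} out of range")
    return (X - ed.mean) @ ed.eigenvectors[:, modes]


def cosine_content(projection: np.ndarray, mode_rank: int = 1) -> float:
    """Cosine content of a projection series (discrete Hess form).

    c_k = (2/T) * (sum_t cos(k*pi*(t+1/2)/T) p_t)^2 / sum_t p_t^2, in [0, 1].
    ``mode_rank`` is 1-based (mode k is compared against a k-half-period
    cosine).  Sample points sit at half-integers so the discrete cosine sums
    to exactly zero over the window and a constant projection scores 0.
    An all-zero projection returns 0 with a warning.
    """
    p = np.asarray(projection, dtype=np.float64).ravel()
    T = p.size
    denom = float(np.sum(p * p))
    if denom == 0.0:
        import warnings
        warnings.warn("all-zero projection; cosine content defined as 0",
                      stacklevel=2)
        return 0.0
    t = np.arange(T) + 0.5
    num = float(np.sum(np.cos(mode_rank * np.pi * t / T) * p)) ** 2
    return min(1.0, (2.0 / T) * num / denom)


def subspace_overlap(vectors_a: np.ndarray, vectors_b: np.ndarray) -> float:
    """Root-mean-square inner product of two orthonormal mode sets.

    1 for identical essential subspaces, 0 for mutually orthogonal ones.
    """
    A = np.asarray(vectors_a, dtype=np.float64)
    B = np.asarray(vectors_b, dtype=np.float64)
    if A.shape != B.shape:
        raise ValueError(f"subspace shape mismatch {A.shape} vs {B.shape}")
    dots = A.T @ B                            # (m, m) inner products
    m = A.shape[1]
    return float(np.sqrt(np.sum(dots ** 2) / m))


def split_half_diagnostics(trajs: list[Trajectory] | Trajectory,
                           selection: Selection,
                           n_modes: int = 2) -> SamplingDiagnostics:
    """Convergence diagnostics: essential-subspace overlap between the two
    halves of the pooled trajectory, and cosine content of the full-run
    projections on the first ``n_modes`` modes."""
    X = _pooled_coords(trajs, selection)
    half = X.shape[0] // 2
    if half < 2:
        raise ValueError("need at least 4 frames for split-half diagnostics")

    def _modes(Y: np.ndarray) -> np.ndarray:
        Yc = Y - Y.mean(axis=0)
        evals, evecs = np.linalg.eigh((Yc.T @ Yc) / Y.shape[0])
        return _fix_signs(evecs[:, np.argsort(evals)[::-1][:n_modes]])

    overlap = subspace_overlap(_modes(X[:half]), _modes(X[half:]))
    ed = fit_pca(trajs, selection)
    proj = project_trajectory(trajs, ed, modes=list(range(n_modes)))
    cc = np.array([cosine_content(proj[:, k], mode_rank=k + 1)
                   for k in range(n_modes)])
    return SamplingDiagnostics(split_half_overlap=overlap, cosine_contents=cc)
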