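"""Independent brute-force reference implementations used as test oracles.

These deliberately favour clarity over speed and share no code with the
package implementations they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_df(frames: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """Naive two-pass double-loop distance-fluctuation matrix (population
    variance of pairwise distances)."""
    x = frames[:, indices, :]
    F, n = x.shape[0], x.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.sqrt(np.sum((x[:, i, :] - x[:, j, :]) ** 2, axis=1))
            mu = d.sum() / F
            out[i, j] = out[j, i] = np.sum((d - mu) ** 2) / F
    return out


def brute_force_rmsip(A: np.ndarray, B: np.ndarray) -> float:
    """Double-loop root-mean-square inner product of two mode sets."""
    m = A.shape[1]
    s = 0.0
    for i in range(m):
        for j in range(m):
            s += float(np.dot(A[:, i], B[:, j])) ** 2
    return float(np.sqrt(s / m))


def brute_force_gromos(rmsd_matrix: np.ndarray, cutoff: float):
    """Greedy neighbour-count clustering straight from the textual recipe:
    repeatedly take the structure with the most neighbours within the
    cutoff (lowest index on ties) as a cluster centre, remove the cluster,
    until the pool is empty.  Returns (assignment, centers)."""
    F = rmsd_matrix.shape[0]
    pool = set(range(F))
    assignment = np.full(F, -1, dtype=int)
    centers = []
    cid = 0
    while pool:
        best, best_n = None, -1
        for i in sorted(pool):
            n = sum(1 for j in pool if rmsd_matrix[i, j] <= cutoff)
            if n > best_n:
                best, best_n = i, n
        members = [j for j in sorted(pool) if rmsd_matrix[best, j] <= cutoff]
        for j in members:
            assignment[j] = cid
        centers.append(best)
        pool -= set(members)
        cid += 1
    return assignment, centers


def brute_force_gyration_axes(coords: np.ndarray):
    """Eigen-decomposition of the gyration tensor by explicit summation."""
    c = coords.mean(axis=0)
    T = np.zeros((3, 3))
    for p in coords - c:
        T += np.outer(p, p)
    T /= coords.shape[0]
    evals, evecs = np.linalg.eigh(T)
    return evals[::-1], evecs[:, ::-1].T


def brute_force_collectivity(u: np.ndarray) -> float:
    p = u ** 2 / np.sum(u ** 2)
    H = -sum(pi * np.log(pi) for pi in p if pi > 0)
    return float(np.exp(H) / len(u))


def path_graph_laplacian_spectrum(n: int) -> np.ndarray:
    """Closed-form eigenvalues of the path-graph Laplacian:
    2 - 2 cos(pi k / n), k = 0..n-1."""
    k = np.arange(n)
    return 2.0 - 2.0 * np.cos(np.pi * k / n)
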