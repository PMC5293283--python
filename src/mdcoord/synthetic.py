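"""Synthetic trajectory generators with known ground truth.

The analyses in this package were designed for microsecond-scale MD
ensembles of a two-subunit, multi-domain receptor.  Those trajectories are
far too large to ship, so every analysis stage is validated against
synthetic ensembles whose statistical or geometric ground truth is known by
construction:

* Gaussian ensembles with prescribed block covariance (distance-fluctuation
  and mutual-information structure),
* rigid two-domain hinges with a deterministic torsion sweep,
* ideal aromatic ring pairs at prescribed centroid distance and interplanar
  angle,
* two-state conformational switches with known state populations,
* tagged metal-site particles for pair-distance series.

All generators are pure functions of (spec, seed); no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import MDFormatError, StructureModel, Trajectory

__all__ = [
    "GaussianEnsembleSpec",
    "HingeSpec",
    "RingPairSpec",
    "SwitchSpec",
    "make_calpha_chain",
    "make_two_domain_structure",
    "make_ring_pair_structure",
    "generate_gaussian_ensemble",
    "generate_hinge_trajectory",
    "hinge_sweep_angles",
    "generate_ring_pair",
    "generate_switch_trajectory",
]


# --------------------------------------------------------------------------
# Structure builders
# --------------------------------------------------------------------------

def _structure_from_arrays(coords, names, resnames, resids, chains, elements,
                           het=None, title="synthetic") -> StructureModel:
    n = len(coords)
    return StructureModel(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids, dtype=int),
        icodes=np.array([""] * n, dtype=object),
        chains=np.array(chains, dtype=object),
        altlocs=np.array([""] * n, dtype=object),
        coords=np.asarray(coords, dtype=np.float64),
        het=np.zeros(n, dtype=bool) if het is None else np.asarray(het, bool),
        title=title)


def make_calpha_chain(n_res: int, chain: str = "A", start_resid: int = 1,
                      origin: Sequence[float] = (0.0, 0.0, 0.0),
                      axis: Sequence[float] = (0.0, 0.0, 1.0),
                      title: str = "synthetic chain") -> StructureModel:
    """An ideal Calpha helix (radius 2.3 Å, rise 1.5 Å, 100°/residue) along
    ``axis`` — a compact, non-collinear backbone stand-in."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    # orthonormal frame around the axis
    ref = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(a, ref); u /= np.linalg.norm(u)
    v = np.cross(a, u)
    t = np.arange(n_res)
    ang = np.deg2rad(100.0) * t
    pts = (np.asarray(origin, dtype=float)
           + np.outer(1.5 * t - 0.75 * n_res, a)
           + np.outer(2.3 * np.cos(ang), u)
           + np.outer(2.3 * np.sin(ang), v))
    return _structure_from_arrays(
        pts, ["CA"] * n_res, ["ALA"] * n_res,
        list(range(start_resid, start_resid + n_res)),
        [chain] * n_res, ["C"] * n_res, title=title)


def make_two_domain_structure(n_a: int = 40, n_b: int = 40,
                              separation: float = 25.0) -> StructureModel:
    """Two helical Calpha domains: chain A along z at the origin, chain B
    along y centred at (separation, 0, 0).

    The inter-centroid line is the x axis, so a hinge rotation of chain B
    about x changes the inter-domain torsion angle by exactly the applied
    rotation.
    """
    dom_a = make_calpha_chain(n_a, chain="A", axis=(0, 0, 1))
    dom_b = make_calpha_chain(n_b, chain="B", axis=(0, 1, 0),
                              origin=(separation, 0.0, 0.0))
    coords = np.vstack([dom_a.coords, dom_b.coords])
    # re-centre each domain exactly on its nominal centroid
    coords[:n_a] -= dom_a.coords.mean(axis=0)
    coords[n_a:] += np.array([separation, 0, 0]) - dom_b.coords.mean(axis=0)
    return _structure_from_arrays(
        coords, ["CA"] * (n_a + n_b), ["ALA"] * (n_a + n_b),
        list(range(1, n_a + 1)) + list(range(1, n_b + 1)),
        ["A"] * n_a + ["B"] * n_b, ["C"] * (n_a + n_b),
        title="synthetic two-domain protein")


_RING_NAMES = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]


def _hexagon(radius: float = 1.39) -> np.ndarray:
    ang = np.deg2rad(60.0 * np.arange(6))
    return np.stack([radius * np.cos(ang), radius * np.sin(ang),
                     np.zeros(6)], axis=1)


def make_ring_pair_structure(distance: float, theta_deg: float) -> StructureModel:
    """Two ideal six-membered aromatic rings (named as Tyr ring atoms).

    Ring 1 lies in the xy plane at the origin (normal = z); ring 2 is
    centred ``distance`` Å along z with its plane tilted by ``theta_deg``
    about the x axis, so the interplanar angle is exactly ``theta_deg``.
    """
    if distance <= 0:
        raise ValueError("centroid distance must be positive")
    if not (0.0 <= theta_deg <= 90.0):
        raise ValueError("interplanar angle must lie in [0, 90] degrees")
    ring1 = _hexagon()
    th = np.deg2rad(theta_deg)
    rot_x = np.array([[1, 0, 0],
                      [0, np.cos(th), -np.sin(th)],
                      [0, np.sin(th), np.cos(th)]])
    ring2 = _hexagon() @ rot_x.T + np.array([0.0, 0.0, distance])
    coords = np.vstack([ring1, ring2])
    return _structure_from_arrays(
        coords, _RING_NAMES * 2, ["TYR"] * 12,
        [1] * 6 + [1] * 6, ["A"] * 6 + ["B"] * 6, ["C"] * 12,
        title="synthetic aromatic ring pair")


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianEnsembleSpec:
    """Gaussian displacement ensemble around a base structure.

    The atom-atom covariance (per Cartesian coordinate, Å²) is either given
    in full or built from a block partition: ``variance`` on the diagonal,
    ``variance * intra_rho`` between atoms of the same block and
    ``variance * inter_rho`` across blocks.  x, y and z displacements are
    independent with identical covariance.
    """

    base: StructureModel
    n_frames: int
    seed: int
    covariance: np.ndarray | None = None
    blocks: tuple[tuple[int, ...], ...] | None = None
    variance: float = 0.04
    intra_rho: float = 0.0
    inter_rho: float = 0.0

    def atom_covariance(self) -> np.ndarray:
        n = self.base.n_atoms
        if self.covariance is not None:
            C = np.asarray(self.covariance, dtype=np.float64)
            if C.shape != (n, n):
                raise ValueError(f"covariance must be ({n}, {n})")
            return C
        C = np.full((n, n), self.variance * self.inter_rho)
        if self.blocks:
            for block in self.blocks:
                idx = np.asarray(block, dtype=int)
                C[np.ix_(idx, idx)] = self.variance * self.intra_rho
        np.fill_diagonal(C, self.variance)
        return C


@dataclass(frozen=True)
class HingeSpec:
    """Rigid two-domain hinge with a deterministic sinusoidal torsion sweep.

    Domain B is rotated about ``axis_point + s*axis_dir`` by
    ``amplitude_deg * sin(2*pi*t/F)``; with F a multiple of 4 the sweep hits
    ±amplitude exactly.  Isotropic Gaussian noise of ``noise_sigma`` Å is
    added per atom after the rotation.
    """

    structure: StructureModel
    domain_b_indices: tuple[int, ...]
    axis_point: tuple[float, float, float]
    axis_dir: tuple[float, float, float]
    amplitude_deg: float
    n_frames: int
    seed: int
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.amplitude_deg < 180.0):
            raise ValueError("amplitude must lie in [0, 180) degrees")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


@dataclass(frozen=True)
class RingPairSpec:
    """Aromatic ring pair at exact (distance, theta) before jitter."""

    distance: float
    theta_deg: float
    n_frames: int
    seed: int
    jitter_sigma: float = 0.0


@dataclass(frozen=True)
class SwitchSpec:
    """Two-state conformational switch with Bernoulli state occupancy."""

    conformer_a: np.ndarray
    conformer_b: np.ndarray
    p_a: float
    n_frames: int
    seed: int
    structure: StructureModel | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_a <= 1.0):
            raise ValueError("state probability must lie in [0, 1]")


# --------------------------------------------------------------------------
# Generators
# --------------------------------------------------------------------------

def _psd_factor(C: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD matrix; raises on negative spectrum."""
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    if w.min() < -1e-8 * max(1.0, abs(w.max())):
        raise ValueError(f"covariance is not positive semi-definite "
                         f"(min eigenvalue {w.min():.3g})")
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T


def generate_gaussian_ensemble(spec: GaussianEnsembleSpec) -> Trajectory:
    """Sample ``n_frames`` displacement frames from the prescribed covariance.

    Bit-reproducible for a given seed.
    """
    if spec.n_frames < 2:
        raise ValueError("Gaussian ensemble needs at least 2 frames")
    C = spec.atom_covariance()
    A = _psd_factor(C)
    rng = np.random.default_rng(spec.seed)
    n = spec.base.n_atoms
    # (F, N, 3): each Cartesian axis an independent draw with covariance C
    z = rng.standard_normal((spec.n_frames, 3, n))
    disp = np.einsum("fci,ni->fnc", z, A)
    frames = spec.base.coords[None, :, :] + disp
    return Trajectory(spec.base, frames, replica=f"gauss-seed{spec.seed}")


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    a = axis / np.linalg.norm(axis)
    x, y, z = a
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C]])


def hinge_sweep_angles(spec: HingeSpec) -> np.ndarray:
    """The deterministic rotation applied at each frame (degrees)."""
    t = np.arange(spec.n_frames)
    return spec.amplitude_deg * np.sin(2.0 * np.pi * t / spec.n_frames)


def generate_hinge_trajectory(spec: HingeSpec) -> Trajectory:
    """Rotate domain B about the hinge axis through a ±amplitude sweep."""
    axis = np.asarray(spec.axis_dir, dtype=float)
    if np.linalg.norm(axis) < 1e-12:
        raise ValueError("hinge axis direction has zero length")
    point = np.asarray(spec.axis_point, dtype=float)
    idx_b = np.asarray(spec.domain_b_indices, dtype=int)
    rng = np.random.default_rng(spec.seed)
    base = spec.structure.coords
    frames = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    for f, ang in enumerate(np.deg2rad(hinge_sweep_angles(spec))):
        R = _rotation_about_axis(axis, ang)
        frames[f, idx_b] = (base[idx_b] - point) @ R.T + point
    if spec.noise_sigma > 0:
        frames += rng.normal(0.0, spec.noise_sigma, size=frames.shape)
    return Trajectory(spec.structure, frames, replica=f"hinge-seed{spec.seed}")


def generate_ring_pair(spec: RingPairSpec) -> Trajectory:
    """Two ideal hexagonal rings built at exactly (distance, theta), with
    optional per-atom Gaussian jitter applied in the lab frame."""
    structure = make_ring_pair_structure(spec.distance, spec.theta_deg)
    rng = np.random.default_rng(spec.seed)
    frames = np.repeat(structure.coords[None, :, :], spec.n_frames, axis=0)
    if spec.jitter_sigma > 0:
        frames += rng.normal(0.0, spec.jitter_sigma, size=frames.shape)
    return Trajectory(structure, frames, replica=f"rings-seed{spec.seed}")


def generate_switch_trajectory(spec: SwitchSpec):
    """Each frame is conformer A with probability ``p_a``, else conformer B.

    Returns ``(trajectory, labels)`` where ``labels[f]`` is 0 for A, 1 for B.
    """
    A = np.asarray(spec.conformer_a, dtype=np.float64)
    B = np.asarray(spec.conformer_b, dtype=np.float64)
    if A.shape != B.shape:
        raise ValueError("conformers must have identical shapes")
    if np.allclose(A, B):
        import warnings
        warnings.warn("switch conformers are identical; states are "
                      "indistinguishable", stacklevel=2)
    rng = np.random.default_rng(spec.seed)
    labels = (rng.random(spec.n_frames) >= spec.p_a).astype(int)
    frames = np.where(labels[:, None, None] == 0, A[None], B[None])
    structure = spec.structure
    if structure is None:
        n = A.shape[0]
        structure = _structure_from_arrays(
            A, ["CA"] * n, ["ALA"] * n, list(range(1, n + 1)),
            ["A"] * n, ["C"] * n, title="synthetic switch")
    return Trajectory(structure, frames,
                      replica=f"switch-seed{spec.seed}"), labels
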