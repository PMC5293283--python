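"""Scalar and vector trajectory descriptors.

Covers the structural observables used to compare liganded states of a
multidomain receptor: radius of gyration, tagged pair distances (including
HETATM metal particles such as the Mn2+ ions at the MIDAS/ADMIDAS sites),
domain principal axes and the inter-domain torsion angle, aromatic
ring-stacking geometry (centroid distance and interplanar angle), and
hydrogen-bond / salt-bridge occupancies.

Atom labels use the ``chain:resid:name`` convention, e.g. ``"B:335:O"`` for
a backbone carbonyl oxygen or ``"X:1:MN"`` for a metal particle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Selection, SelectionError, StructureModel, Trajectory

__all__ = [
    "DescriptorSeries", "StackingGeometry", "ContactOccupancy", "DomainAxes",
    "radius_of_gyration", "pair_distance_series", "principal_axes",
    "interdomain_torsion_series", "stacking_series",
    "hbond_occupancy", "salt_bridge_occupancy", "hbond_saltbridge_occupancy",
    "histogram_series",
]

# Aromatic ring heavy atoms per residue type.  The Trp centroid uses all 9
# bicyclic heavy atoms by default; the 6-membered ring alone is an option.
RING_ATOMS = {
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}
TRP_SIX_RING = ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")

# Stacking-geometry windows (Å, degrees)
PAIRING_DISTANCE_A = 12.0
STACKING_DISTANCE_A = (4.9, 10.4)
STACKING_THETA_DEG = (1.2, 89.9)

# Contact criteria (Å, degrees); standard defaults, overridable per call
HBOND_DISTANCE_A = 3.5
HBOND_ANGLE_DEG = 120.0
SALTBRIDGE_DISTANCE_A = 4.0

_HBOND_DONOR_NAMES = {"N", "ND1", "ND2", "NE", "NE1", "NE2", "NH1", "NH2",
                      "NZ", "OG", "OG1", "OH", "SG", "OW"}
_HBOND_ACCEPTOR_NAMES = {"O", "OD1", "OD2", "OE1", "OE2", "ND1", "NE2",
                         "OG", "OG1", "OH", "SD", "OXT", "OW"}
_BASIC_N = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",),
            "HIS": ("ND1", "NE2")}
_ACIDIC_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


@dataclass
class DescriptorSeries:
    """A named per-frame scalar series with units."""

    name: str
    values: np.ndarray
    unit: str = "A"
    replica: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"descriptor {self.name}: non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(self.values.size),
                             self.name: self.values})


@dataclass
class StackingGeometry:
    """Per-frame aromatic pair geometry with pairing/stacking flags."""

    pair: tuple[str, str]
    distance: np.ndarray        # Å
    theta: np.ndarray           # degrees, [0, 90]
    paired: np.ndarray          # distance < 12 Å
    stacked: np.ndarray         # distance in [4.9, 10.4] Å, theta in [1.2, 89.9]
    replica: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(self.distance.size),
            "distance": self.distance, "theta": self.theta,
            "paired": self.paired, "stacked": self.stacked})


@dataclass
class ContactOccupancy:
    """A donor/acceptor (or charged-group) contact and its time occupancy."""

    donor: str
    acceptor: str
    kind: str                   # "hbond" | "saltbridge"
    present: np.ndarray         # per-frame bool over pooled replica frames
    occupancy: float            # % of analyzed time

    @classmethod
    def from_mask(cls, donor: str, acceptor: str, kind: str,
                  present: np.ndarray) -> "ContactOccupancy":
        present = np.asarray(present, dtype=bool)
        return cls(donor, acceptor, kind, present,
                   100.0 * float(present.mean()))


@dataclass
class DomainAxes:
    """Per-frame centroids and orthonormal principal axes of two domains,
    plus the inter-domain torsion series."""

    centroids_a: np.ndarray     # (F, 3)
    centroids_b: np.ndarray
    axes_a: np.ndarray          # (F, 3, 3), rows = axes, descending extent
    axes_b: np.ndarray
    torsion: np.ndarray         # (F,) degrees in [0, 180]


# --------------------------------------------------------------------------
# Label resolution
# --------------------------------------------------------------------------

def resolve_atom(structure: StructureModel, label: str) -> int:
    """Resolve ``chain:resid[:name]`` to a single atom index."""
    parts = label.split(":")
    if len(parts) == 2:
        chain, resid = parts
        name = None
    elif len(parts) == 3:
        chain, resid, name = parts
    else:
        raise SelectionError(f"atom label '{label}' is not chain:resid[:name]")
    mask = ((structure.chains.astype(str) == chain)
            & (structure.resids == int(resid)))
    if name is not None:
        mask &= structure.names.astype(str) == name
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"atom label '{label}' matches no atom")
    if idx.size > 1:
        raise SelectionError(f"atom label '{label}' is ambiguous "
                             f"({idx.size} atoms); add the atom name")
    return int(idx[0])


# --------------------------------------------------------------------------
# Scalar descriptors
# --------------------------------------------------------------------------

def radius_of_gyration(traj: Trajectory, selection: Selection) -> DescriptorSeries:
    """Unweighted Rg per frame: sqrt(mean squared distance to the centroid)."""
    idx = selection.array
    if idx.size == 0:
        raise SelectionError("empty selection for radius of gyration")
    x = traj.frames[:, idx, :]
    c = x.mean(axis=1, keepdims=True)
    rg = np.sqrt(np.mean(np.sum((x - c) ** 2, axis=2), axis=1))
    return DescriptorSeries("radius_of_gyration", rg, "A", traj.replica)


def pair_distance_series(traj: Trajectory, atom_a: str,
                         atom_b: str) -> DescriptorSeries:
    """Euclidean distance per frame between two labelled atoms (works for
    HETATM metal particles)."""
    ia = resolve_atom(traj.reference, atom_a)
    ib = resolve_atom(traj.reference, atom_b)
    d = np.linalg.norm(traj.frames[:, ia, :] - traj.frames[:, ib, :], axis=1)
    return DescriptorSeries(f"dist[{atom_a}--{atom_b}]", d, "A", traj.replica)


# --------------------------------------------------------------------------
# Principal axes and inter-domain torsion
# --------------------------------------------------------------------------

def principal_axes(coords: np.ndarray, selection: Selection | None = None):
    """Centroid and principal axes of a coordinate set.

    Axes are the eigenvectors of the gyration tensor, rows ordered by
    descending extent, with a deterministic sign (largest-magnitude
    component positive).  Degenerate eigenvalues are resolved by numpy's
    stable ascending eigenvalue order.
    """
    x = np.asarray(coords, dtype=np.float64)
    if selection is not None:
        x = x[selection.array]
    if x.shape[0] < 3:
        raise ValueError("need at least 3 atoms for principal axes")
    c = x.mean(axis=0)
    x0 = x - c
    if np.linalg.matrix_rank(x0, tol=1e-10) < 2:
        raise ValueError("collinear atom set; principal axes underdetermined")
    gyr = (x0.T @ x0) / x.shape[0]
    evals, evecs = np.linalg.eigh(gyr)
    order = np.argsort(evals, kind="stable")[::-1]
    axes = evecs[:, order].T           # rows = axes, descending eigenvalue
    for k in range(3):
        i = int(np.argmax(np.abs(axes[k])))
        if axes[k, i] < 0:
            axes[k] = -axes[k]
    return c, axes, evals[order]


def _dihedral(p0, p1, p2, p3) -> float:
    """Dihedral angle of four points, degrees in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise ValueError("coincident centroids; torsion undefined")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return float(np.degrees(np.arctan2(np.dot(np.cross(b1, v), w),
                                       np.dot(v, w))))


def _body_signed_axes(coords: np.ndarray, sel: Selection):
    """Principal axes signed against body-fixed reference vectors.

    The sign of each axis is set by its projection on internal direction
    vectors (last-first atom, then first-atom-to-centroid), so the result
    is equivariant under global rotations and stable from frame to frame
    for quasi-rigid domains — lab-frame sign rules would flip arbitrarily
    under per-frame rigid motion.
    """
    x = coords[sel.array]
    c, axes, evals = principal_axes(x)
    ref1 = x[-1] - x[0]
    ref2 = x[0] - c
    for k in range(3):
        s = float(np.dot(axes[k], ref1))
        if abs(s) < 1e-9:
            s = float(np.dot(axes[k], ref2))
        if s < 0:
            axes[k] = -axes[k]
    return c, axes, evals


def interdomain_torsion_series(traj: Trajectory, domain_a: Selection,
                               domain_b: Selection,
                               return_axes: bool = False):
    """Torsion angle between two domains' leading principal axes.

    Per frame, tip = centroid + first principal axis; the torsion is the
    dihedral (tip_a, centroid_a, centroid_b, tip_b) reported as a magnitude
    in [0, 180] degrees.  Axis signs are fixed against body-internal
    reference vectors (and kept continuous with the previous frame), which
    prevents 180-degree jumps and makes the series exactly invariant under
    per-frame global rigid motion.
    """
    F = traj.n_frames
    cents_a = np.empty((F, 3)); cents_b = np.empty((F, 3))
    axes_a = np.empty((F, 3, 3)); axes_b = np.empty((F, 3, 3))
    for f in range(F):
        ca, aa, _ = _body_signed_axes(traj.frames[f], domain_a)
        cb, ab, _ = _body_signed_axes(traj.frames[f], domain_b)
        cents_a[f], cents_b[f] = ca, cb
        axes_a[f], axes_b[f] = aa, ab
    torsion = np.empty(F)
    for f in range(F):
        ang = _dihedral(cents_a[f] + axes_a[f, 0], cents_a[f],
                        cents_b[f], cents_b[f] + axes_b[f, 0])
        torsion[f] = abs(ang)
    series = DescriptorSeries("interdomain_torsion", torsion, "deg",
                              traj.replica)
    if return_axes:
        return series, DomainAxes(cents_a, cents_b, axes_a, axes_b, torsion)
    return series


# --------------------------------------------------------------------------
# Aromatic stacking geometry
# --------------------------------------------------------------------------

def _ring_indices(structure: StructureModel, chain: str, resid: int,
                  trp_six_ring: bool) -> np.ndarray:
    mask = ((structure.chains.astype(str) == chain)
            & (structure.resids == int(resid)))
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"residue {chain}:{resid} not found")
    resname = str(structure.resnames[idx[0]])
    if resname not in RING_ATOMS:
        raise SelectionError(f"residue {chain}:{resid} ({resname}) has no "
                             f"aromatic ring")
    wanted = (TRP_SIX_RING if (resname == "TRP" and trp_six_ring)
              else RING_ATOMS[resname])
    names = structure.names[idx].astype(str)
    ring = idx[np.isin(names, wanted)]
    if ring.size < len(wanted):
        missing = set(wanted) - set(names.tolist())
        raise SelectionError(f"residue {chain}:{resid}: missing ring atoms "
                             f"{sorted(missing)}")
    return ring


def _plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the total-least-squares plane (smallest eigenvector of
    the centred covariance)."""
    x0 = points - points.mean(axis=0)
    evals, evecs = np.linalg.eigh(x0.T @ x0)
    return evecs[:, 0]


def stacking_series(traj: Trajectory, residue_a: tuple[str, int],
                    residue_b: tuple[str, int],
                    trp_six_ring: bool = False,
                    pairing_cutoff: float = PAIRING_DISTANCE_A,
                    stack_distance: tuple[float, float] = STACKING_DISTANCE_A,
                    stack_theta: tuple[float, float] = STACKING_THETA_DEG,
                    ) -> StackingGeometry:
    """Centroid distance and interplanar angle of two aromatic residues.

    The centroid is the mean of the ring heavy atoms (all 9 bicyclic atoms
    for Trp unless ``trp_six_ring``); theta is the acute angle between the
    best-fit ring planes, folded to [0, 90] degrees and independent of
    atom ordering and normal sign.  ``paired`` flags centroid distances
    below 12 Å; ``stacked`` flags the stacking/T-shaped window
    (4.9-10.4 Å, 1.2-89.9 degrees).
    """
    s = traj.reference
    ring_a = _ring_indices(s, *residue_a, trp_six_ring=trp_six_ring)
    ring_b = _ring_indices(s, *residue_b, trp_six_ring=trp_six_ring)
    F = traj.n_frames
    dist = np.empty(F); theta = np.empty(F)
    for f in range(F):
        pa = traj.frames[f, ring_a]
        pb = traj.frames[f, ring_b]
        dist[f] = np.linalg.norm(pa.mean(axis=0) - pb.mean(axis=0))
        cosang = abs(float(np.dot(_plane_normal(pa), _plane_normal(pb))))
        theta[f] = np.degrees(np.arccos(min(1.0, cosang)))
    eps = 1e-9      # keep exact window-edge geometries inside the window
    paired = dist < pairing_cutoff
    stacked = ((dist >= stack_distance[0] - eps)
               & (dist <= stack_distance[1] + eps)
               & (theta >= stack_theta[0] - eps)
               & (theta <= stack_theta[1] + eps))
    lab_a = f"{residue_a[0]}:{residue_a[1]}"
    lab_b = f"{residue_b[0]}:{residue_b[1]}"
    return StackingGeometry((lab_a, lab_b), dist, theta, paired, stacked,
                            traj.replica)


# --------------------------------------------------------------------------
# Hydrogen bonds and salt bridges
# --------------------------------------------------------------------------

def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Angle a-b-c per frame, degrees."""
    v1 = a - b
    v2 = c - b
    cosang = np.sum(v1 * v2, axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def hbond_occupancy(trajs: list[Trajectory] | Trajectory,
                    pairs: list[tuple],
                    distance_cutoff: float = HBOND_DISTANCE_A,
                    angle_cutoff: float = HBOND_ANGLE_DEG) -> list[ContactOccupancy]:
    """Occupancy of explicit donor/acceptor pairs over pooled replica frames.

    Each pair is ``(donor_label, acceptor_label)`` or
    ``(donor_label, acceptor_label, hydrogen_label)``.  With a hydrogen the
    criterion is donor-acceptor distance <= cutoff and donor-H...acceptor
    angle >= angle_cutoff; without hydrogens the distance criterion alone is
    used.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    out = []
    for pair in pairs:
        donor, acceptor = pair[0], pair[1]
        hydrogen = pair[2] if len(pair) > 2 else None
        masks = []
        for traj in trajs:
            ia = resolve_atom(traj.reference, donor)
            ib = resolve_atom(traj.reference, acceptor)
            d = np.linalg.norm(traj.frames[:, ia] - traj.frames[:, ib], axis=1)
            ok = d <= distance_cutoff
            if hydrogen is not None:
                ih = resolve_atom(traj.reference, hydrogen)
                ang = _angle_deg(traj.frames[:, ia], traj.frames[:, ih],
                                 traj.frames[:, ib])
                ok &= ang >= angle_cutoff
            masks.append(ok)
        out.append(ContactOccupancy.from_mask(
            donor, acceptor, "hbond", np.concatenate(masks)))
    return out


def _charged_atoms(structure: StructureModel, sel: Selection, table: dict):
    idx = sel.array
    out = []
    for i in idx:
        resname = str(structure.resnames[i])
        if resname in table and str(structure.names[i]) in table[resname]:
            out.append(int(i))
    return out


def salt_bridge_occupancy(trajs: list[Trajectory] | Trajectory,
                          selection_a: Selection, selection_b: Selection,
                          cutoff: float = SALTBRIDGE_DISTANCE_A
                          ) -> list[ContactOccupancy]:
    """Auto-scan salt bridges between two selections.

    A bridge exists in a frame when any basic nitrogen (Arg NE/NH1/NH2,
    Lys NZ, His ND1/NE2) of one residue lies within ``cutoff`` of any
    carboxylate oxygen (Asp OD1/OD2, Glu OE1/OE2) of the other.  Occupancy
    is reported per residue pair over pooled replica frames.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    s = trajs[0].reference
    basic = (_charged_atoms(s, selection_a, _BASIC_N)
             + [-i - 1 for i in _charged_atoms(s, selection_b, _BASIC_N)])
    # group atoms by residue, keeping track of which side they came from
    def _by_residue(atoms, structure):
        groups: dict[tuple, list[int]] = {}
        for i in atoms:
            j = i if i >= 0 else -i - 1
            key = (str(structure.chains[j]), int(structure.resids[j]),
                   "a" if i >= 0 else "b")
            groups.setdefault(key, []).append(j)
        return groups

    basic_res = _by_residue(basic, s)
    acidic = (_charged_atoms(s, selection_a, _ACIDIC_O)
              + [-i - 1 for i in _charged_atoms(s, selection_b, _ACIDIC_O)])
    acidic_res = _by_residue(acidic, s)
    out = []
    for bkey, batoms in sorted(basic_res.items()):
        for akey, aatoms in sorted(acidic_res.items()):
            if bkey[2] == akey[2]:
                continue              # same side of the interface
            masks = []
            for traj in trajs:
                present = np.zeros(traj.n_frames, dtype=bool)
                for i in batoms:
                    for j in aatoms:
                        d = np.linalg.norm(traj.frames[:, i] - traj.frames[:, j],
                                           axis=1)
                        present |= d <= cutoff
                masks.append(present)
            donor = f"{bkey[0]}:{bkey[1]}"
            acceptor = f"{akey[0]}:{akey[1]}"
            out.append(ContactOccupancy.from_mask(
                donor, acceptor, "saltbridge", np.concatenate(masks)))
    return out


def hbond_saltbridge_occupancy(trajs: list[Trajectory] | Trajectory,
                               hbond_pairs: list[tuple] | None = None,
                               interface: tuple[Selection, Selection] | None = None,
                               min_occupancy: float = 1.0,
                               **kwargs) -> list[ContactOccupancy]:
    """Combined H-bond (explicit pairs) and salt-bridge (interface auto-scan)
    occupancy table, filtered at ``min_occupancy`` percent."""
    results: list[ContactOccupancy] = []
    if hbond_pairs:
        results += hbond_occupancy(trajs, hbond_pairs,
                                   **{k: v for k, v in kwargs.items()
                                      if k in ("distance_cutoff", "angle_cutoff")})
    if interface is not None:
        results += salt_bridge_occupancy(trajs, *interface,
                                         **{k: v for k, v in kwargs.items()
                                            if k == "cutoff"})
    if not results:
        import warnings
        warnings.warn("no candidate contact pairs", stacklevel=2)
    return [c for c in results if c.occupancy >= min_occupancy]


# --------------------------------------------------------------------------
# Histograms (distribution summaries of descriptor series)
# --------------------------------------------------------------------------

def histogram_series(series: DescriptorSeries | np.ndarray,
                     bins: int | str = "fd",
                     density: bool = False) -> pd.DataFrame:
    """Histogram of a descriptor series (default Freedman-Diaconis binning)."""
    values = series.values if isinstance(series, DescriptorSeries) else series
    counts, edges = np.histogram(values, bins=bins, density=density)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})
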