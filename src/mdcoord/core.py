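"""Structures, trajectories, selections and superposition.

This module is the shared substrate of the analysis stack: a light-weight
PDB structure model (author numbering, altloc policy, insertion codes),
trajectory containers with replica metadata, a small selection language
("chain B and resid 55-108 353-434 and name CA"), domain bookkeeping,
Kabsch superposition and RMSD.

Internal units are Angstrom everywhere.  Binary trajectory formats (DCD,
XTC) are read and written through MDAnalysis coordinate readers; XTC files
store nanometres and are converted on read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np

logger = logging.getLogger("mdcoord")

__all__ = [
    "MDFormatError",
    "SelectionError",
    "StructureModel",
    "Trajectory",
    "DomainDefinition",
    "Selection",
    "read_structure",
    "read_trajectory",
    "write_pdb",
    "write_multimodel_pdb",
    "write_dcd",
    "resolve_selection",
    "kabsch",
    "superpose_trajectory",
    "rmsd",
]


class MDFormatError(ValueError):
    """Raised on malformed structure/trajectory input."""


class SelectionError(ValueError):
    """Raised when a selection cannot be resolved to a non-empty atom set."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class StructureModel:
    """Ordered atom records of one structure (coordinates in Angstrom).

    The residue key is (chain, residue number, insertion code) in author
    (PDB) numbering; atom records additionally carry name, altloc, element
    and a HETATM flag so metal sites (e.g. Mn2+ at MIDAS/ADMIDAS) resolve
    like any other atom.
    """

    names: np.ndarray          # (N,) str
    elements: np.ndarray       # (N,) str
    resnames: np.ndarray       # (N,) str
    resids: np.ndarray         # (N,) int, author numbering
    icodes: np.ndarray         # (N,) str
    chains: np.ndarray         # (N,) str
    altlocs: np.ndarray        # (N,) str
    coords: np.ndarray         # (N, 3) float64, Angstrom
    het: np.ndarray            # (N,) bool
    title: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise MDFormatError("coordinates must have shape (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise MDFormatError("non-finite coordinates in structure")
        keys = list(zip(self.chains.tolist(), self.resids.tolist(),
                        self.icodes.tolist(), self.names.tolist(),
                        self.altlocs.tolist()))
        if len(set(keys)) != len(keys):
            raise MDFormatError(
                "duplicate (chain, resid, icode, atom name, altloc) records")

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[0])

    def subset(self, indices: Sequence[int]) -> "StructureModel":
        idx = np.asarray(indices, dtype=int)
        return StructureModel(
            names=self.names[idx], elements=self.elements[idx],
            resnames=self.resnames[idx], resids=self.resids[idx],
            icodes=self.icodes[idx], chains=self.chains[idx],
            altlocs=self.altlocs[idx], coords=self.coords[idx],
            het=self.het[idx], title=self.title)

    def atom_labels(self, indices: Sequence[int] | None = None) -> list[str]:
        """``chain:resnum`` labels (insertion code appended when present)."""
        idx = np.arange(self.n_atoms) if indices is None else np.asarray(indices)
        return [
            f"{self.chains[i]}:{self.resids[i]}{self.icodes[i].strip()}"
            for i in idx
        ]


@dataclass
class Trajectory:
    """Fixed-topology coordinate frames with replica/time metadata."""

    reference: StructureModel
    frames: np.ndarray                 # (F, N, 3) Angstrom
    times: np.ndarray | None = None    # (F,) ps, optional
    replica: str = "replica-1"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise MDFormatError("frames must have shape (F, N, 3)")
        if self.frames.shape[0] < 1:
            raise MDFormatError("trajectory must contain at least one frame")
        if self.frames.shape[1] != self.reference.n_atoms:
            raise MDFormatError(
                f"frame atom count {self.frames.shape[1]} != structure "
                f"atom count {self.reference.n_atoms}")
        if not np.all(np.isfinite(self.frames)):
            raise MDFormatError("non-finite coordinates in trajectory")
        if self.times is None:
            self.times = np.arange(self.frames.shape[0], dtype=np.float64)
        else:
            self.times = np.asarray(self.times, dtype=np.float64)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])


@dataclass(frozen=True)
class DomainDefinition:
    """A named set of residue-number intervals on one chain (author numbering,
    inclusive bounds)."""

    name: str
    chain: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        ivals = tuple((int(a), int(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", ivals)
        for a, b in ivals:
            if a > b:
                raise ValueError(f"interval {a}-{b} reversed in domain {self.name}")
        ordered = sorted(ivals)
        for (a1, b1), (a2, b2) in zip(ordered, ordered[1:]):
            if a2 <= b1:
                raise ValueError(
                    f"overlapping intervals {a1}-{b1} and {a2}-{b2} "
                    f"in domain {self.name}")

    def contains(self, resid: int) -> bool:
        return any(a <= resid <= b for a, b in self.intervals)


@dataclass(frozen=True)
class Selection:
    """Sorted, unique atom indices plus the expression that produced them."""

    indices: tuple[int, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if list(idx) != sorted(set(idx)):
            raise ValueError("selection indices must be unique and sorted")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


# --------------------------------------------------------------------------
# PDB reading/writing (fixed-column ATOM/HETATM, MODEL/ENDMDL)
# --------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        altloc = line[16:17].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip()
        resid = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            # fall back on the leading characters of the atom-name field
            element = "".join(c for c in line[12:14] if c.isalpha())
    except (ValueError, IndexError) as exc:
        raise MDFormatError(f"line {lineno}: unparseable PDB record: {exc}") from exc
    return name, altloc, resname, chain, resid, icode, (x, y, z), element


def _read_models(text: Iterable[str]):
    """Yield lists of parsed atom tuples, one list per MODEL (or one list for
    a model-less file)."""
    current: list = []
    saw_model = False
    n_dropped_altloc = 0
    for lineno, raw in enumerate(text, start=1):
        rec = raw[:6].strip()
        if rec == "MODEL":
            if saw_model and current:
                yield current, n_dropped_altloc
                current, n_dropped_altloc = [], 0
            saw_model = True
        elif rec == "ENDMDL":
            yield current, n_dropped_altloc
            current, n_dropped_altloc = [], 0
        elif rec in ("ATOM", "HETATM"):
            parsed = _parse_atom_line(raw, lineno)
            if parsed[1] not in ("", "A"):      # altloc policy: keep 'A'/blank
                n_dropped_altloc += 1
                continue
            current.append((rec == "HETATM",) + parsed)
    if current:
        yield current, n_dropped_altloc


def _model_from_records(records, title: str) -> StructureModel:
    het, names, alts, resnames, chains, resids, icodes, coords, elements = (
        [], [], [], [], [], [], [], [], [])
    for h, name, altloc, resname, chain, resid, icode, xyz, element in records:
        het.append(h); names.append(name); alts.append(altloc)
        resnames.append(resname); chains.append(chain); resids.append(resid)
        icodes.append(icode); coords.append(xyz); elements.append(element)
    return StructureModel(
        names=np.array(names, dtype=object), elements=np.array(elements, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids, dtype=int), icodes=np.array(icodes, dtype=object),
        chains=np.array(chains, dtype=object), altlocs=np.array(alts, dtype=object),
        coords=np.array(coords, dtype=np.float64),
        het=np.array(het, dtype=bool), title=title)


def read_structure(pdb_source: Union[str, Path, TextIO], title: str = "") -> StructureModel:
    """Read the first model of a PDB file into a :class:`StructureModel`.

    Altloc policy: records with altloc other than blank or 'A' are dropped
    (the number of dropped records is logged).  Malformed mandatory columns
    raise :class:`MDFormatError` naming the offending line.
    """
    if hasattr(pdb_source, "read"):
        lines = pdb_source.read().splitlines()
    else:
        path = Path(pdb_source)
        lines = path.read_text().splitlines()
        title = title or path.stem
    models = list(_read_models(lines))
    if not models:
        raise MDFormatError("no ATOM/HETATM records found (empty PDB source)")
    records, dropped = models[0]
    if not records:
        raise MDFormatError("first model contains no atoms")
    if dropped:
        logger.info("read_structure: dropped %d non-'A' altloc records", dropped)
    return _model_from_records(records, title)


def _read_pdb_trajectory(structure: StructureModel, lines: Iterable[str]) -> np.ndarray:
    frames = []
    for i, (records, _) in enumerate(_read_models(lines)):
        if not records:
            continue
        if len(records) != structure.n_atoms:
            raise MDFormatError(
                f"model {i + 1} has {len(records)} atoms, structure has "
                f"{structure.n_atoms}; last good frame: {len(frames)}")
        frames.append([rec[7] for rec in records])
    if not frames:
        raise MDFormatError("no models found in multi-model PDB")
    return np.array(frames, dtype=np.float64)


def _read_binary_trajectory(structure: StructureModel, path: Path):
    """DCD/XTC through MDAnalysis standalone coordinate readers.

    MDAnalysis converts to its native Angstrom unit on read, which covers
    the nm-to-Angstrom conversion for XTC.
    """
    if path.suffix.lower() == ".dcd":
        from MDAnalysis.coordinates.DCD import DCDReader as Reader
    else:
        from MDAnalysis.coordinates.XTC import XTCReader as Reader
    reader = Reader(str(path))
    if reader.n_atoms != structure.n_atoms:
        reader.close()
        raise MDFormatError(
            f"trajectory has {reader.n_atoms} atoms, structure has "
            f"{structure.n_atoms}")
    frames, times = [], []
    try:
        for ts in reader:
            frames.append(np.array(ts.positions, dtype=np.float64))
            times.append(float(ts.time))
    except Exception as exc:  # truncated/corrupt tail
        raise MDFormatError(
            f"error reading frame {len(frames)}; last good frame: "
            f"{len(frames) - 1}") from exc
    finally:
        reader.close()
    if not frames:
        raise MDFormatError(f"no frames in trajectory {path}")
    return np.array(frames), np.array(times)


def read_trajectory(structure: StructureModel,
                    source: Union[str, Path],
                    replica: str = "replica-1") -> Trajectory:
    """Read a DCD, XTC or multi-model PDB trajectory against ``structure``.

    The atom count of every frame must match the structure; coordinates are
    normalized to Angstrom.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".dcd", ".xtc"):
        frames, times = _read_binary_trajectory(structure, path)
        return Trajectory(structure, frames, times, replica)
    frames = _read_pdb_trajectory(structure, path.read_text().splitlines())
    return Trajectory(structure, frames, None, replica)


_PDB_FMT = ("{rec:<6s}{serial:>5d} {name:<4s}{alt:1s}{resname:<3s} {chain:1s}"
            "{resid:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            "          {element:>2s}\n")


def _format_atom(i: int, s: StructureModel, xyz: np.ndarray) -> str:
    name = str(s.names[i])
    # PDB convention: atom names of <4 chars start in column 14
    name_field = name if len(name) >= 4 else f" {name:<3s}"
    return _PDB_FMT.format(
        rec="HETATM" if s.het[i] else "ATOM", serial=(i % 99999) + 1,
        name=name_field, alt=str(s.altlocs[i]) or " ",
        resname=str(s.resnames[i]), chain=str(s.chains[i]) or " ",
        resid=int(s.resids[i]), icode=str(s.icodes[i]) or " ",
        x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0, b=0.0,
        element=str(s.elements[i]))


def write_pdb(structure: StructureModel, path: Union[str, Path],
              coords: np.ndarray | None = None) -> None:
    """Write a single-model PDB file."""
    xyz = structure.coords if coords is None else np.asarray(coords)
    with open(path, "w") as fh:
        if structure.title:
            fh.write(f"TITLE     {structure.title}\n")
        for i in range(structure.n_atoms):
            fh.write(_format_atom(i, structure, xyz[i]))
        fh.write("END\n")


def write_multimodel_pdb(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write a trajectory as a multi-model PDB (exercises the PDB reader)."""
    s = traj.reference
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:>4d}\n")
            for i in range(s.n_atoms):
                fh.write(_format_atom(i, s, traj.frames[f, i]))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_dcd(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write trajectory frames to a DCD file (Angstrom, via MDAnalysis)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    u = mda.Universe.empty(traj.n_atoms, trajectory=True)
    u.load_new(traj.frames.astype(np.float32), format=MemoryReader)
    with mda.Writer(str(path), n_atoms=traj.n_atoms) as w:
        for _ in u.trajectory:
            w.write(u.atoms)


# --------------------------------------------------------------------------
# Selections
# --------------------------------------------------------------------------

def _parse_resid_tokens(tokens: list[str]) -> list[tuple[int, int]]:
    out = []
    for tok in tokens:
        if "-" in tok[1:]:  # allow negative single numbers
            a, b = tok.rsplit("-", 1)
            out.append((int(a), int(b)))
        else:
            out.append((int(tok), int(tok)))
    return out


def _apply_expression(structure: StructureModel, expr: str) -> np.ndarray:
    mask = np.ones(structure.n_atoms, dtype=bool)
    for clause in expr.split(" and "):
        tokens = clause.split()
        if not tokens:
            continue
        key, args = tokens[0].lower(), tokens[1:]
        if key == "all":
            continue
        if not args:
            raise SelectionError(f"clause '{clause}' has no arguments")
        if key == "chain":
            mask &= np.isin(structure.chains.astype(str), args)
        elif key == "resid":
            ivals = _parse_resid_tokens(args)
            m = np.zeros(structure.n_atoms, dtype=bool)
            for a, b in ivals:
                m |= (structure.resids >= a) & (structure.resids <= b)
            mask &= m
        elif key == "name":
            mask &= np.isin(structure.names.astype(str), args)
        elif key == "resname":
            mask &= np.isin(structure.resnames.astype(str), args)
        elif key == "element":
            mask &= np.isin(structure.elements.astype(str), args)
        else:
            raise SelectionError(f"unknown selection keyword '{key}'")
    return mask


def resolve_selection(structure: StructureModel,
                      expr: Union[str, DomainDefinition],
                      atom_filter: str | None = None) -> Selection:
    """Resolve a selection expression or :class:`DomainDefinition` to a
    deterministic, ordered atom-index list.

    ``atom_filter`` restricts to an atom name (e.g. ``"CA"``).  An empty
    result raises :class:`SelectionError` — the usual symptom of a wrong
    chain id or residue numbering.
    """
    if isinstance(expr, DomainDefinition):
        mask = structure.chains.astype(str) == expr.chain
        m = np.zeros(structure.n_atoms, dtype=bool)
        for a, b in expr.intervals:
            m |= (structure.resids >= a) & (structure.resids <= b)
        mask &= m
        provenance = (f"domain {expr.name}: chain {expr.chain} resid "
                      + " ".join(f"{a}-{b}" for a, b in expr.intervals))
    else:
        mask = _apply_expression(structure, expr)
        provenance = expr
    if atom_filter:
        mask &= structure.names.astype(str) == atom_filter
        provenance += f" [{atom_filter} only]"
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection resolved to no atoms: {provenance}")
    return Selection(tuple(int(i) for i in idx), provenance)


# --------------------------------------------------------------------------
# Superposition and RMSD
# --------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` minimizes the RMSD.
    ``R`` is a proper rotation (det = +1): the SVD sign is corrected so a
    mirror image is never matched by reflection.
    """
    P = np.asarray(mobile, dtype=np.float64)
    Q = np.asarray(target, dtype=np.float64)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("kabsch expects two (n, 3) arrays of equal shape")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    if np.linalg.matrix_rank(P0, tol=1e-10) < 2:
        raise ValueError("fit atoms are collinear; rotation underdetermined")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - cp @ R.T
    return R, t


def superpose_trajectory(traj: Trajectory, reference: StructureModel,
                         fit_selection: Selection) -> Trajectory:
    """Rigid-body fit of every frame onto ``reference`` over ``fit_selection``.

    Proper rotations only; the post-fit RMSD over the fit set never exceeds
    the pre-fit RMSD.
    """
    idx = fit_selection.array
    ref = reference.coords[idx]
    out = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        R, t = kabsch(traj.frames[f, idx], ref)
        out[f] = traj.frames[f] @ R.T + t
    return Trajectory(traj.reference, out, traj.times, traj.replica)


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
         selection: Selection | None = None, fit: bool = False) -> float:
    """Root-mean-square deviation (Angstrom) over ``selection``, optionally
    after least-squares superposition."""
    A = np.asarray(coords_a, dtype=np.float64)
    B = np.asarray(coords_b, dtype=np.float64)
    if A.shape != B.shape:
        raise ValueError(f"coordinate shape mismatch {A.shape} vs {B.shape}")
    if selection is not None:
        A, B = A[selection.array], B[selection.array]
    if fit:
        R, t = kabsch(A, B)
        A = A @ R.T + t
    return float(math.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))
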