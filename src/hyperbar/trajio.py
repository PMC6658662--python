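"""Trajectory, topology and index-group I/O.

One in-memory data model serves every analysis stage: a :class:`Topology`
(per-atom metadata shared by all frames), a sequence of :class:`Frame`
objects (coordinates in nm plus a rectangular periodic box), and
:class:`IndexGroup` selections. File serials are 1-based (GRO/PDB/NDX
convention); in-memory indices are 0-based — the boundary is the
reader/writer.

Lengths are nm everywhere inside the package; Å appears only at PDB I/O.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "IndexGroup",
    "TrajioError",
    "ParseError",
    "SelectionError",
    "VDW_RADII_NM",
    "read_gro",
    "write_gro",
    "read_pdb_frame",
    "write_pdb",
    "read_ndx",
    "write_ndx",
    "select",
    "guess_element",
]


class TrajioError(Exception):
    """Base error for trajectory I/O and selection."""


class ParseError(TrajioError):
    """Malformed file content; message names the offending line."""


class SelectionError(TrajioError):
    """A selection resolved to nothing, or serials fell outside the topology."""


#: Default van der Waals radii per element, nm (Bondi-style values; He uses
#: the LJ sigma/2 of a monatomic gas site rounded to 0.14 nm). Per-atom
#: override is available through Topology.vdw_radii.
VDW_RADII_NM: dict[str, float] = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "P": 0.180,
    "S": 0.180,
    "HE": 0.140,
    "NE": 0.154,
    "AR": 0.188,
    "NA": 0.227,
    "K": 0.275,
    "CL": 0.175,
    "MG": 0.173,
    "CA": 0.231,
}
_DEFAULT_VDW = 0.150

#: Atomic masses (u) for the elements the pipeline touches.
MASSES_U: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "HE": 4.0026,
    "NE": 20.180,
    "AR": 39.948,
    "NA": 22.990,
    "K": 39.098,
    "CL": 35.45,
    "MG": 24.305,
    "CA": 40.078,
}
_DEFAULT_MASS = 12.011


def guess_element(atom_name: str, residue_name: str = "") -> str:
    """Guess an element symbol from a GRO/PDB atom name.

    Monatomic species (He, Na, Cl, ...) are recognised through their residue
    name first, so that e.g. calcium ions are not mistaken for alpha-carbons.
    """
    rn = residue_name.strip().upper()
    if rn in VDW_RADII_NM and rn not in ("C", "N", "O", "H", "P", "S"):
        return rn
    name = atom_name.strip().upper()
    if name[:2] in ("HE", "NE", "AR", "NA", "CL", "MG"):
        # two-letter element only when the name is exactly the element
        if name in ("HE", "NE", "AR", "NA", "CL", "MG"):
            return name
    for ch in name:
        if ch.isalpha():
            return ch
    raise ParseError(f"cannot infer element from atom name {atom_name!r}")


@dataclass(frozen=True)
class Atom:
    """Per-atom metadata. ``serial`` is the 1-based file serial."""

    serial: int
    name: str
    residue_name: str
    residue_number: int
    chain_id: str = ""
    element: str = ""
    mass: float = 0.0
    vdw_radius: float = 0.0

    def __post_init__(self):
        if self.serial < 1:
            raise ValueError("atom serial must be positive")


class Topology:
    """Columnar per-atom metadata shared by every frame of a trajectory."""

    def __init__(self, atoms: Iterable[Atom]):
        atoms = list(atoms)
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            raise TrajioError("duplicate atom serials in topology")
        self.atoms: list[Atom] = atoms
        self.names = np.array([a.name for a in atoms])
        self.residue_names = np.array([a.residue_name for a in atoms])
        self.residue_numbers = np.array([a.residue_number for a in atoms], dtype=int)
        self.chain_ids = np.array([a.chain_id for a in atoms])
        self.elements = np.array(
            [a.element or guess_element(a.name, a.residue_name) for a in atoms]
        )
        self.masses = np.array(
            [a.mass if a.mass > 0 else MASSES_U.get(e, _DEFAULT_MASS)
             for a, e in zip(atoms, self.elements)]
        )
        self.vdw_radii = np.array(
            [a.vdw_radius if a.vdw_radius > 0 else VDW_RADII_NM.get(e, _DEFAULT_VDW)
             for a, e in zip(atoms, self.elements)]
        )
        if np.any(self.masses <= 0) or np.any(self.vdw_radii <= 0):
            raise TrajioError("masses and vdW radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class Frame:
    """One trajectory frame: time (ps), coordinates (N,3) nm, box edges (3,) nm."""

    time: float
    coordinates: np.ndarray
    box: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise TrajioError("coordinates must be (N, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise TrajioError("box must be three positive edge lengths")

    def copy(self) -> "Frame":
        return Frame(self.time, self.coordinates.copy(), self.box.copy())


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self):
        n = self.topology.n_atoms
        for i, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n:
                raise TrajioError(
                    f"frame {i} has {fr.coordinates.shape[0]} atoms, topology has {n}"
                )
        times = [fr.time for fr in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise TrajioError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])


@dataclass
class IndexGroup:
    """A named, ordered group of 1-based atom serials (GROMACS NDX semantics)."""

    name: str
    atom_serials: tuple[int, ...]

    def __post_init__(self):
        self.atom_serials = tuple(int(s) for s in self.atom_serials)
        if len(set(self.atom_serials)) != len(self.atom_serials):
            raise TrajioError(f"duplicate serials in group {self.name!r}")
        if any(s < 1 for s in self.atom_serials):
            raise TrajioError(f"non-positive serial in group {self.name!r}")

    def indices(self, topology: Topology | None = None) -> np.ndarray:
        """0-based indices; validates against the topology size when given."""
        idx = np.array(self.atom_serials, dtype=int) - 1
        if topology is not None and (len(idx) and idx.max() >= topology.n_atoms):
            raise SelectionError(
                f"group {self.name!r} references serial "
                f"{idx.max() + 1} beyond topology size {topology.n_atoms}"
            )
        return idx

    def __len__(self) -> int:
        return len(self.atom_serials)


# ---------------------------------------------------------------------------
# GRO

def _parse_gro_time(title: str) -> float | None:
    if "t=" in title:
        try:
            return float(title.rsplit("t=", 1)[1].split()[0])
        except (ValueError, IndexError):
            return None
    return None


def read_gro(path) -> Trajectory:
    """Read a (possibly multi-frame) GROMACS GRO file.

    Coordinates are returned in nm exactly as stored (3-decimal precision).
    Only rectangular boxes are supported: box lines with more than three
    fields must have zeros in the off-diagonal entries.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[Frame] = []
    atoms: list[Atom] | None = None
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        try:
            n = int(lines[i + 1].strip())
        except (IndexError, ValueError):
            raise ParseError(f"line {i + 2}: expected atom count")
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ParseError(f"line {i + 2}: truncated frame (expected {n} atoms)")
        coords = np.empty((n, 3))
        frame_atoms: list[Atom] = []
        for j, ln in enumerate(body):
            if len(ln) < 44:
                raise ParseError(f"line {i + 3 + j}: GRO record too short")
            try:
                resnum = int(ln[0:5])
                resname = ln[5:10].strip()
                name = ln[10:15].strip()
                serial = int(ln[15:20])
                coords[j] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
            except ValueError as exc:
                raise ParseError(f"line {i + 3 + j}: {exc}") from exc
            if atoms is None:
                # GRO serials wrap at 100000; renumber sequentially
                frame_atoms.append(
                    Atom(serial=j + 1, name=name, residue_name=resname,
                         residue_number=resnum)
                )
        box_line = lines[i + 2 + n].split()
        if len(box_line) < 3:
            raise ParseError(f"line {i + 3 + n}: box line needs 3 fields")
        if len(box_line) > 3 and any(abs(float(v)) > 1e-12 for v in box_line[3:]):
            raise ParseError(
                f"line {i + 3 + n}: triclinic boxes are not supported"
            )
        box = np.array([float(v) for v in box_line[:3]])
        if atoms is None:
            atoms = frame_atoms
        elif n != len(atoms):
            raise TrajioError(
                f"frame {frame_no} has {n} atoms; first frame had {len(atoms)}"
            )
        t = _parse_gro_time(title)
        frames.append(Frame(t if t is not None else float(frame_no), coords, box))
        i += n + 3
        frame_no += 1
    if atoms is None:
        raise ParseError("empty GRO file")
    return Trajectory(Topology(atoms), frames)


def write_gro(trajectory: Trajectory, path, title: str = "hyperbar system") -> None:
    """Write a multi-frame GRO file (3-decimal nm, GROMACS fixed columns)."""
    top = trajectory.topology
    with open(path, "w") as fh:
        for fr in trajectory.frames:
            fh.write(f"{title} t= {fr.time:.5f}\n{top.n_atoms:5d}\n")
            for k in range(top.n_atoms):
                a = top.atoms[k]
                x, y, z = fr.coordinates[k]
                fh.write(
                    f"{a.residue_number % 100000:5d}{a.residue_name:<5.5s}"
                    f"{a.name:>5.5s}{a.serial % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            fh.write(f"{fr.box[0]:10.5f}{fr.box[1]:10.5f}{fr.box[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# PDB

def write_pdb(frame: Frame, topology: Topology, path) -> None:
    """Write one frame as a PDB file (coordinates nm -> Å).

    Serials above 99999 wrap modulo 100000 (documented policy; hybrid-36 is
    not needed for the systems this package builds).
    """
    if frame.coordinates.shape[0] != topology.n_atoms:
        raise TrajioError("frame does not match topology")
    with open(path, "w") as fh:
        bx = frame.box * 10.0
        fh.write(
            f"CRYST1{bx[0]:9.3f}{bx[1]:9.3f}{bx[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        for k, a in enumerate(topology.atoms):
            x, y, z = frame.coordinates[k] * 10.0
            name = a.name if len(a.name) == 4 else f" {a.name:<3.3s}"
            fh.write(
                f"ATOM  {a.serial % 100000:5d} {name:<4.4s} "
                f"{a.residue_name:<3.3s} {(a.chain_id or 'X')[:1]}"
                f"{a.residue_number % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {a.element[:2]:>2.2s}\n"
            )
        fh.write("END\n")


def read_pdb_frame(path) -> tuple[Topology, Frame]:
    """Read a single-model PDB file (fixture support; coordinates Å -> nm)."""
    atoms: list[Atom] = []
    rows: list[tuple[float, float, float]] = []
    box = np.array([100.0, 100.0, 100.0])
    with open(path) as fh:
        for lineno, ln in enumerate(fh, 1):
            if ln.startswith("CRYST1"):
                box = np.array([float(ln[6:15]), float(ln[15:24]), float(ln[24:33])]) / 10.0
            elif ln.startswith(("ATOM  ", "HETATM")):
                try:
                    atoms.append(
                        Atom(
                            serial=len(atoms) + 1,
                            name=ln[12:16].strip(),
                            residue_name=ln[17:20].strip(),
                            residue_number=int(ln[22:26]),
                            chain_id=ln[21].strip(),
                        )
                    )
                    rows.append(
                        (float(ln[30:38]) / 10.0, float(ln[38:46]) / 10.0,
                         float(ln[46:54]) / 10.0)
                    )
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: {exc}") from exc
            elif ln.startswith(("ENDMDL", "END")):
                break
    if not atoms:
        raise ParseError("no ATOM records found")
    return Topology(atoms), Frame(0.0, np.array(rows), box)


# ---------------------------------------------------------------------------
# NDX

def read_ndx(path) -> list[IndexGroup]:
    """Read GROMACS NDX index groups (bracketed names, 1-based serials)."""
    groups: list[IndexGroup] = []
    name: str | None = None
    serials: list[int] = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, 1):
            ln = ln.split(";")[0].strip()
            if not ln:
                continue
            if ln.startswith("["):
                if not ln.endswith("]"):
                    raise ParseError(f"line {lineno}: unterminated group header")
                if name is not None:
                    if not serials:
                        warnings.warn(f"NDX group {name!r} is empty")
                    groups.append(IndexGroup(name, tuple(serials)))
                name = ln[1:-1].strip()
                serials = []
            else:
                if name is None:
                    raise ParseError(f"line {lineno}: serials before any group header")
                try:
                    serials.extend(int(tok) for tok in ln.split())
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: {exc}") from exc
    if name is not None:
        if not serials:
            warnings.warn(f"NDX group {name!r} is empty")
        groups.append(IndexGroup(name, tuple(serials)))
    return groups


def write_ndx(groups: Sequence[IndexGroup], path) -> None:
    with open(path, "w") as fh:
        for g in groups:
            fh.write(f"[ {g.name} ]\n")
            for i in range(0, len(g.atom_serials), 15):
                fh.write(" ".join(str(s) for s in g.atom_serials[i : i + 15]) + "\n")


# ---------------------------------------------------------------------------
# Selection

def select(
    topology: Topology,
    name: str | None = None,
    chain: str | None = None,
    residue_name: str | None = None,
    residue_number: int | None = None,
    stride: int = 1,
    group_name: str | None = None,
) -> IndexGroup:
    """Conjunctive atom selection over the topology.

    Criteria are ANDed: atom name, chain id, residue name, residue number.
    ``stride`` keeps every stride-th atom *of the matches* (1 = all), which is
    how reference sets like "every 5th Cα of a chain" are expressed. Raises
    :class:`SelectionError` when nothing matches — an empty selection is
    never returned silently.
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    if name is not None:
        mask &= topology.names == name
    if chain is not None:
        mask &= topology.chain_ids == chain
    if residue_name is not None:
        mask &= topology.residue_names == residue_name
    if residue_number is not None:
        mask &= topology.residue_numbers == int(residue_number)
    idx = np.nonzero(mask)[0]
    if stride > 1:
        idx = idx[::stride]
    if len(idx) == 0:
        raise SelectionError(
            f"selection matched no atoms (name={name}, chain={chain}, "
            f"residue_name={residue_name}, residue_number={residue_number})"
        )
    label = group_name or "_".join(
        str(v) for v in (name, chain, residue_name, residue_number) if v is not None
    )
    return IndexGroup(label, tuple(int(i) + 1 for i in idx))
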