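"""Structures, trajectories and their file formats.

Atomic structures are read from PDB text (via gemmi) into a flat list of
:class:`AtomRecord`, with van der Waals radii resolved from an element
table and alternate locations reduced to the highest-occupancy conformer.
Trajectories use a small documented plain-text frame format (see
:func:`write_trajectory`); an adapter converting an MDAnalysis Universe to
the same :class:`Trajectory` contract covers standard binary formats.

Conventions: orthorhombic boxes only, coordinates in angstrom wrapped into
[0, L) per axis, times in ps with a uniform frame spacing ``dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import gemmi

__all__ = [
    "FormatError", "TopologyError", "TimingError", "ResolutionError",
    "DEFAULT_VDW", "AtomRecord", "Structure", "BoxDims", "Frame",
    "Topology", "Trajectory", "read_structure", "write_structure",
    "read_trajectory", "write_trajectory", "trajectory_from_mdanalysis",
]


class FormatError(ValueError):
    """A file does not conform to the expected text format."""


class TopologyError(ValueError):
    """Frame content is inconsistent with the declared topology."""


class TimingError(ValueError):
    """Frame times are not uniformly spaced."""


class ResolutionError(KeyError):
    """An element could not be resolved to a vdW radius."""


# Bondi-style radii (A); "*" is the fallback for anything unlisted.
DEFAULT_VDW: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "H": 1.20, "P": 1.80, "*": 1.80,
}


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    resname: str
    chain_id: str
    resseq: int
    icode: str
    altloc: str
    xyz: np.ndarray            # (3,) A
    occupancy: float
    vdw_radius: float          # A, > 0 after resolution
    charge: float = 0.0        # e

    def __post_init__(self):
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise ValueError(f"atom {self.serial} has non-finite coordinates")
        object.__setattr__(self, "xyz", xyz)
        if not self.vdw_radius > 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be > 0")

    @property
    def residue_id(self) -> tuple[str, str, int, str]:
        """(chain, resname, resseq, icode) — the residue this atom belongs to."""
        return (self.chain_id, self.resname, self.resseq, self.icode)

    @property
    def key(self) -> tuple[str, int, str, str, str]:
        return (self.chain_id, self.resseq, self.icode, self.name, self.altloc)


@dataclass
class Structure:
    """An ordered collection of atoms, optionally with a Cn symmetry hint."""

    atoms: list[AtomRecord]
    symmetry_hint: int | None = None

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("Structure must contain at least one atom")
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set = set()
            dup = next(k for k in keys if k in seen or seen.add(k))
            raise ValueError(f"duplicate atom identity {dup}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    @property
    def vdw(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    @property
    def chain_ids(self) -> list[str]:
        """Distinct chain identifiers in order of first appearance."""
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def select(self, predicate: Callable[[AtomRecord], bool]) -> "Structure":
        kept = [a for a in self.atoms if predicate(a)]
        if not kept:
            raise ValueError("selection matches no atoms")
        return Structure(kept, symmetry_hint=self.symmetry_hint)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Apply x -> R x + t to every atom; returns a new Structure."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        atoms = [replace(a, xyz=R @ a.xyz + t) for a in self.atoms]
        return Structure(atoms, symmetry_hint=self.symmetry_hint)


@dataclass(frozen=True)
class BoxDims:
    Lx: float
    Ly: float
    Lz: float

    def __post_init__(self):
        if not (self.Lx > 0 and self.Ly > 0 and self.Lz > 0):
            raise ValueError("box dimensions must be strictly positive")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.Lx, self.Ly, self.Lz])

    @property
    def area_xy(self) -> float:
        return self.Lx * self.Ly


@dataclass
class Frame:
    time: float                # ps
    box: BoxDims
    coords: np.ndarray         # (N, 3) A, wrapped into [0, L)

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3 or not np.all(np.isfinite(c)):
            raise ValueError("coords must be a finite (N, 3) array")
        self.coords = np.mod(c, self.box.lengths)


@dataclass
class Topology:
    names: list[str]
    charges: np.ndarray        # (N,) e

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        if len(self.names) != len(self.charges):
            raise TopologyError("names and charges must have equal length")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.frames:
            raise FormatError("trajectory must contain at least one frame")
        n = len(self.topology)
        for i, f in enumerate(self.frames):
            if f.coords.shape[0] != n:
                raise TopologyError(
                    f"frame {i} has {f.coords.shape[0]} atoms, topology has {n}")
        times = np.array([f.time for f in self.frames])
        if len(times) >= 2:
            dts = np.diff(times)
            if np.any(dts <= 0):
                raise TimingError("frame times must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                raise TimingError("frame spacing is not uniform")

    @property
    def dt(self) -> float:
        if len(self.frames) < 2:
            raise TimingError("dt undefined for a single-frame trajectory")
        return self.frames[1].time - self.frames[0].time

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def box(self) -> BoxDims:
        return self.frames[0].box

    def coords_array(self) -> np.ndarray:
        """All frames stacked as an (n_frames, N, 3) array."""
        return np.stack([f.coords for f in self.frames])


# ---------------------------------------------------------------------------
# structures

def resolve_vdw(element: str, name: str, table: dict[str, float]) -> float:
    """Radius for an element, falling back to the name's first alpha character."""
    el = element.strip().upper()
    if el in table:
        return table[el]
    for ch in name:
        if ch.isalpha():
            if ch.upper() in table:
                return table[ch.upper()]
            break
    if "*" in table:
        return table["*"]
    raise ResolutionError(
        f"no vdW radius for element {element!r} (atom name {name!r})")


def _validate_pdb_lines(path: Path) -> None:
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise FormatError(f"{path}:{lineno}: truncated coordinate record")
        try:
            [float(line[i:j]) for i, j in ((30, 38), (38, 46), (46, 54))]
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: unparseable coordinates in {line[:54]!r}")


def read_structure(path, vdw_table: dict[str, float] | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only the first model is used.  For atoms with alternate locations the
    highest-occupancy conformer is kept (ties broken by altloc letter).
    vdW radii are resolved per element from ``vdw_table``
    (default :data:`DEFAULT_VDW`).
    """
    path = Path(path)
    table = DEFAULT_VDW if vdw_table is None else vdw_table
    _validate_pdb_lines(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    atoms: list[AtomRecord] = []
    if len(st) == 0:
        raise FormatError(f"{path}: no models/atoms found")
    model = st[0]
    for chain in model:
        for res in chain:
            # altloc policy: per atom name keep max occupancy, tie -> letter order
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                by_name.setdefault(at.name, []).append(at)
            for name, alts in by_name.items():
                at = min(alts, key=lambda a: (-a.occ, a.altloc or "~"))
                el = at.element.name if at.element else ""
                atoms.append(AtomRecord(
                    serial=at.serial,
                    name=name,
                    element=el,
                    resname=res.name,
                    chain_id=chain.name,
                    resseq=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    altloc="",
                    xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                    vdw_radius=resolve_vdw(el, name, table),
                    charge=float(at.charge),
                ))
    if not atoms:
        raise FormatError(f"{path}: no ATOM/HETATM records")
    return Structure(atoms)


def write_structure(struct: Structure, path) -> None:
    """Write a Structure as PDB ATOM records (wwPDB v3.3 columns)."""
    lines = []
    for i, a in enumerate(struct.atoms, start=1):
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {i % 100000:5d} {name:<4s}{a.altloc or ' ':1s}"
            f"{a.resname:>3s} {a.chain_id[:1]:1s}{a.resseq % 10000:4d}"
            f"{a.icode or ' ':1s}   "
            f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trajectories
#
# Frame text format (one file = one trajectory):
#
#   # porelumen trajectory v1          <- optional comment lines anywhere
#   TOPOLOGY <N>                       <- optional block: N lines "name charge"
#   FRAME t=<ps> box=<Lx> <Ly> <Lz>    <- one per frame, followed by
#   <x> <y> <z>                        <- exactly N coordinate lines (A)
#
# Coordinates are wrapped into [0, L) on read.

_COORD_FMT = "%.10g"


def write_trajectory(traj: Trajectory, path) -> None:
    """Write the plain-text frame format; lossless to ~10 significant figures."""
    path = Path(path)
    out = ["# porelumen trajectory v1"]
    out.append(f"TOPOLOGY {len(traj.topology)}")
    for name, q in zip(traj.topology.names, traj.topology.charges):
        out.append(f"{name} {_COORD_FMT % q}")
    for f in traj.frames:
        out.append(f"FRAME t={_COORD_FMT % f.time} "
                   f"box={_COORD_FMT % f.box.Lx} {_COORD_FMT % f.box.Ly} "
                   f"{_COORD_FMT % f.box.Lz}")
        for row in f.coords:
            out.append(" ".join(_COORD_FMT % v for v in row))
    try:
        path.write_text("\n".join(out) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write trajectory to {path}: {exc}") from exc


def read_trajectory(path, topology: Topology | None = None) -> Trajectory:
    """Read the plain-text frame format written by :func:`write_trajectory`.

    An explicit ``topology`` argument overrides any TOPOLOGY block in the
    file; one of the two must be present.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    file_topo: Topology | None = None
    frames: list[Frame] = []
    i = 0
    n_lines = len(lines)

    def fail(lineno, msg):
        raise FormatError(f"{path}:{lineno + 1}: {msg}")

    while i < n_lines:
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        if line.startswith("TOPOLOGY"):
            try:
                n = int(line.split()[1])
            except (IndexError, ValueError):
                fail(i, "malformed TOPOLOGY header")
            names, charges = [], []
            for j in range(n):
                try:
                    name, q = lines[i + 1 + j].split()
                except (IndexError, ValueError):
                    fail(i + 1 + j, "malformed topology line")
                names.append(name)
                charges.append(float(q))
            file_topo = Topology(names, np.array(charges))
            i += 1 + n
            continue
        if line.startswith("FRAME"):
            try:
                tokens = line.split()
                t = float(tokens[1].split("=", 1)[1])
                bx = float(tokens[2].split("=", 1)[1])
                by, bz = float(tokens[3]), float(tokens[4])
            except (IndexError, ValueError):
                fail(i, "malformed FRAME header")
            topo = topology or file_topo
            if topo is None:
                fail(i, "FRAME before TOPOLOGY and no topology argument given")
            n = len(topo)
            block = lines[i + 1:i + 1 + n]
            if len(block) < n:
                raise TopologyError(
                    f"{path}: frame at line {i + 1} has {len(block)} "
                    f"coordinate lines, expected {n}")
            coords = np.empty((n, 3))
            for j, cl in enumerate(block):
                parts = cl.split()
                if len(parts) != 3:
                    raise TopologyError(
                        f"{path}:{i + 2 + j}: expected 3 coordinates, "
                        f"got {len(parts)}")
                try:
                    coords[j] = [float(p) for p in parts]
                except ValueError:
                    raise TopologyError(
                        f"{path}:{i + 2 + j}: unparseable coordinate line")
            frames.append(Frame(time=t, box=BoxDims(bx, by, bz), coords=coords))
            i += 1 + n
            continue
        fail(i, f"unrecognized line {line[:40]!r}")

    topo = topology or file_topo
    if topo is None:
        raise FormatError(f"{path}: no topology found")
    return Trajectory(topology=topo, frames=frames)


def trajectory_from_mdanalysis(universe, selection: str = "all") -> Trajectory:
    """Convert an MDAnalysis Universe (any supported format) to a Trajectory.

    Requires an orthorhombic box on every frame; charges are taken from the
    topology when present, else zero.
    """
    group = universe.select_atoms(selection)
    try:
        charges = np.asarray(group.charges, dtype=float)
    except Exception:
        charges = np.zeros(len(group))
    topo = Topology([a.name for a in group.atoms], charges)
    frames = []
    for ts in universe.trajectory:
        dims = ts.dimensions
        if dims is None or not np.allclose(dims[3:6], 90.0, atol=1e-3):
            raise ValueError("only orthorhombic boxes are supported")
        frames.append(Frame(
            time=float(ts.time),
            box=BoxDims(*[float(x) for x in dims[:3]]),
            coords=np.array(group.positions, dtype=float),
        ))
    return Trajectory(topology=topo, frames=frames)
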