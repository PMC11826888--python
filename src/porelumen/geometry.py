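"""Pore-lumen geometry: axis detection, maximal-sphere radius profiles,
constriction rings and their lining residues, membrane depth, and rigid
superposition RMSD.

The radius profile follows the classic maximal-sphere construction: at
each position z along the pore axis the radius is the largest sphere
centered in the plane through z that touches no atom, i.e.
``max_c min_i (|c - x_i| - vdw_i)``.  Unlike the original Monte-Carlo
search, the in-plane optimization here is a deterministic coarse grid
followed by Nelder-Mead refinement, seeded from the previous slice, so
profiles are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.signal import find_peaks
from scipy.spatial.transform import Rotation

from .io import AtomRecord, Structure

__all__ = [
    "AxisFrame", "PoreProfile", "ConstrictionRing", "SuperpositionResult",
    "principal_pore_axis", "radius_profile", "detect_constrictions",
    "lining_residues", "membrane_depth_profile", "superpose_rmsd",
]


@dataclass(frozen=True)
class AxisFrame:
    """An oriented pore axis: origin plus unit direction, with an
    orthonormal in-plane basis for axis coordinates."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, float)
        d = np.asarray(self.direction, float)
        norm = np.linalg.norm(d)
        if abs(norm - 1.0) > 1e-9:
            d = d / norm
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)

    @property
    def basis(self) -> np.ndarray:
        """3x3 matrix whose rows are (u, v, direction)."""
        d = self.direction
        ref = np.array([1.0, 0.0, 0.0])
        if abs(d @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(d, ref)
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        return np.array([u, v, d])

    def to_axis(self, xyz: np.ndarray) -> np.ndarray:
        """World coordinates -> (u, v, z) axis coordinates."""
        return (np.atleast_2d(xyz) - self.origin) @ self.basis.T

    def from_axis(self, uvz: np.ndarray) -> np.ndarray:
        return np.atleast_2d(uvz) @ self.basis + self.origin

    @staticmethod
    def along_z(origin=(0.0, 0.0, 0.0)) -> "AxisFrame":
        return AxisFrame(np.asarray(origin, float), np.array([0.0, 0.0, 1.0]))


def principal_pore_axis(struct: Structure) -> AxisFrame:
    """Pore axis from the inertia tensor of the atom positions.

    The direction is the eigenvector whose eigenvalue is most separated
    from the other two — the unique Cn axis of a symmetric oligomer.  The
    sign is chosen so the direction has a non-negative z component.
    """
    xyz = struct.coords
    if len(xyz) < 4:
        raise ValueError("need at least 4 atoms to determine an axis")
    centroid = xyz.mean(axis=0)
    r = xyz - centroid
    if np.linalg.matrix_rank(r, tol=1e-8) < 2:
        raise ValueError("atoms are collinear; axis undetermined")
    inertia = np.eye(3) * np.sum(r ** 2) - r.T @ r
    evals, evecs = np.linalg.eigh(inertia)
    scale = max(abs(evals).max(), 1e-300)
    gaps = [min(abs(evals[i] - evals[j]) for j in range(3) if j != i)
            for i in range(3)]
    if max(gaps) / scale < 0.01:
        raise ValueError(
            "degenerate inertia spectrum; supply an explicit AxisFrame")
    direction = evecs[:, int(np.argmax(gaps))]
    if direction[2] < 0 or (direction[2] == 0 and (
            direction[0] < 0 or (direction[0] == 0 and direction[1] < 0))):
        direction = -direction
    return AxisFrame(centroid, direction)


@dataclass
class PoreProfile:
    """Radius versus axial position.

    ``flag`` per grid point: ``open`` (a positive-clearance sphere fits),
    ``capped`` (clearance exceeded r_max), ``blocked`` (best clearance is
    negative; the negative value is recorded so occlusion depth remains
    visible, distinguishing a capped vestibule from a 0 A waist).
    """

    z: np.ndarray
    radius: np.ndarray
    center_offset: np.ndarray      # (n, 2) in-plane sphere-center offsets
    flag: np.ndarray               # array of str
    axis: AxisFrame | None = None

    def __post_init__(self):
        if not np.all(np.diff(self.z) > 0):
            raise ValueError("z grid must be strictly increasing")
        open_ = self.flag == "open"
        if np.any(self.radius[open_] < 0):
            raise ValueError("open grid points must have non-negative radius")

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0]) if len(self.z) > 1 else 0.0

    def min_radius(self) -> tuple[float, float]:
        """(radius, z) of the global minimum over open points."""
        open_ = np.flatnonzero(self.flag == "open")
        if len(open_) == 0:
            raise ValueError("no open grid points")
        i = open_[np.argmin(self.radius[open_])]
        return float(self.radius[i]), float(self.z[i])

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "z": self.z, "radius": self.radius,
            "offset_u": self.center_offset[:, 0],
            "offset_v": self.center_offset[:, 1],
            "flag": self.flag})


def _clearance(centers: np.ndarray, atom_uv: np.ndarray, atom_z: np.ndarray,
               vdw: np.ndarray, z: float) -> np.ndarray:
    """min_i (|c - x_i| - vdw_i) for sphere centers in the plane through z.

    ``centers`` is (m, 2) in-plane positions; atoms are given in axis
    coordinates.  Vectorized over centers."""
    d2_inplane = ((centers[:, None, :] - atom_uv[None, :, :]) ** 2).sum(-1)
    dist = np.sqrt(d2_inplane + (atom_z - z) ** 2)
    return (dist - vdw).min(axis=1)


def radius_profile(
    struct: Structure,
    axis: AxisFrame | None = None,
    z_range: tuple[float, float] | None = None,
    dz: float = 0.5,
    mode: str = "optimized",
    r_max: float = 15.0,
    coarse_step: float = 1.0,
    center_bound: float = 5.0,
) -> PoreProfile:
    """Maximal-sphere radius profile along the pore axis.

    mode="axial" evaluates the sphere center on the axis only;
    mode="optimized" maximizes the clearance over in-plane centers by a
    coarse grid (``coarse_step``) followed by Nelder-Mead refinement,
    seeded additionally from the previous slice's optimum.  The center
    may move at most ``center_bound`` from the axis — without that bound
    the maximal sphere would jump out of the lumen wherever the exterior
    of the wall offers more clearance than a constriction.  Radii are
    capped at ``r_max``; slices where even the best center overlaps an
    atom are flagged blocked with the (negative) clearance recorded.
    """
    if len(struct) == 0:
        raise ValueError("empty structure")
    if dz <= 0:
        raise ValueError("dz must be positive")
    if mode not in ("axial", "optimized"):
        raise ValueError(f"unknown mode {mode!r}")
    if axis is None:
        axis = principal_pore_axis(struct)
    uvz = axis.to_axis(struct.coords)
    atom_uv, atom_z = uvz[:, :2], uvz[:, 2]
    vdw = struct.vdw
    vdw_max = float(vdw.max())
    order = np.argsort(atom_z)
    atom_uv, atom_z, vdw = atom_uv[order], atom_z[order], vdw[order]

    if z_range is None:
        z_range = (float(atom_z.min()), float(atom_z.max()))
    z_grid = np.arange(z_range[0], z_range[1] + dz * 0.5, dz)

    # coarse in-plane candidate grid covering the search disk
    ticks = np.arange(-center_bound, center_bound + coarse_step * 0.5,
                      coarse_step)
    gu, gv = np.meshgrid(ticks, ticks)
    coarse = np.column_stack([gu.ravel(), gv.ravel()])
    coarse = coarse[(coarse ** 2).sum(1) <= center_bound ** 2]

    radius = np.empty(len(z_grid))
    offsets = np.zeros((len(z_grid), 2))
    flags = np.empty(len(z_grid), dtype=object)
    prev_center = np.zeros(2)

    for i, z in enumerate(z_grid):
        lo = np.searchsorted(atom_z, z - (r_max + vdw_max))
        hi = np.searchsorted(atom_z, z + (r_max + vdw_max))
        if hi <= lo:
            radius[i], flags[i] = r_max, "capped"
            offsets[i] = 0.0
            continue
        auv, az, av = atom_uv[lo:hi], atom_z[lo:hi], vdw[lo:hi]
        if mode == "axial":
            best_c = np.zeros(2)
            best = float(_clearance(best_c[None], auv, az, av, z)[0])
        else:
            cand = np.vstack([coarse, prev_center[None]])
            vals = _clearance(cand, auv, az, av, z)
            j = int(np.argmax(vals))
            if vals[j] >= r_max:
                best_c, best = cand[j], float(vals[j])
            else:
                # keep the center inside the search disk: outside an open
                # end the clearance grows without bound and the sphere
                # would escape the lumen sideways
                def objective(c):
                    val = _clearance(c[None], auv, az, av, z)[0]
                    overshoot = max(0.0, float(np.hypot(*c)) - center_bound)
                    return -(val - 10.0 * overshoot)

                res = minimize(
                    objective, cand[j], method="Nelder-Mead",
                    options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
                best_c, best = res.x, -res.fun
                if best < vals[j]:      # refinement may not improve
                    best_c, best = cand[j], float(vals[j])
            prev_center = best_c if best < r_max else np.zeros(2)
        offsets[i] = best_c
        if best >= r_max:
            radius[i], flags[i] = r_max, "capped"
        elif best < 0:
            radius[i], flags[i] = best, "blocked"
        else:
            radius[i], flags[i] = best, "open"
    return PoreProfile(z_grid, radius, offsets, flags.astype(str), axis=axis)


@dataclass
class ConstrictionRing:
    """A local minimum of the radius profile — a candidate sensing zone."""

    z_min: float
    radius_min: float
    prominence: float
    center_offset: np.ndarray = field(default_factory=lambda: np.zeros(2))
    lining: list = field(default_factory=list)


def detect_constrictions(
    profile: PoreProfile,
    radius_ceiling: float = 7.0,
    min_prominence: float = 0.5,
    merge_window: float = 4.0,
) -> list[ConstrictionRing]:
    """Local radius minima with minimum prominence, below a ceiling,
    merged within ``merge_window`` keeping the deeper; ordered by z."""
    open_idx = np.flatnonzero(profile.flag == "open")
    if len(open_idx) < 3:
        return []
    rings: list[ConstrictionRing] = []
    # split open points into contiguous runs so capped/blocked gaps
    # cannot fabricate minima across them
    splits = np.flatnonzero(np.diff(open_idx) > 1)
    for run in np.split(open_idx, splits + 1):
        if len(run) < 3:
            continue
        r = profile.radius[run]
        peaks, props = find_peaks(-r, prominence=min_prominence)
        for p, prom in zip(peaks, props["prominences"]):
            if r[p] <= radius_ceiling:
                k = run[p]
                rings.append(ConstrictionRing(
                    z_min=float(profile.z[k]),
                    radius_min=float(profile.radius[k]),
                    prominence=float(prom),
                    center_offset=profile.center_offset[k].copy()))
    rings.sort(key=lambda g: g.z_min)
    # greedy merge: repeatedly drop the shallower of the closest pair
    merged = True
    while merged and len(rings) > 1:
        merged = False
        for a, b in zip(rings, rings[1:]):
            if b.z_min - a.z_min < merge_window:
                rings.remove(a if a.radius_min > b.radius_min else b)
                merged = True
                break
    return rings


def lining_residues(
    struct: Structure,
    axis: AxisFrame,
    ring: ConstrictionRing,
    slab_halfwidth: float = 3.0,
    n_nearest: int = 14,
) -> list[tuple[str, str, int, str]]:
    """Residues owning the ``n_nearest`` atoms by clearance to the ring's
    sphere center within ``|z - z_min| <= slab_halfwidth``, deduplicated
    in order of increasing clearance (one entry per protomer expected for
    Cn-symmetric pores)."""
    uvz = axis.to_axis(struct.coords)
    in_slab = np.abs(uvz[:, 2] - ring.z_min) <= slab_halfwidth
    idx = np.flatnonzero(in_slab)
    if len(idx) == 0:
        return []
    center = np.array([ring.center_offset[0], ring.center_offset[1], ring.z_min])
    clear = np.linalg.norm(uvz[idx] - center, axis=1) - struct.vdw[idx]
    nearest = idx[np.argsort(clear, kind="stable")][:n_nearest]
    residues: list[tuple[str, str, int, str]] = []
    for i in nearest:
        rid = struct.atoms[i].residue_id
        if rid not in residues:
            residues.append(rid)
    return residues


# side-chain terminal atoms for standard residues; fallback is all
# non-backbone atoms (or every atom for single-bead residues)
_TERMINAL_ATOMS = {
    "ALA": {"CB"}, "ARG": {"NH1", "NH2"}, "ASN": {"OD1", "ND2"},
    "ASP": {"OD1", "OD2"}, "CYS": {"SG"}, "GLN": {"OE1", "NE2"},
    "GLU": {"OE1", "OE2"}, "GLY": {"CA"}, "HIS": {"ND1", "NE2"},
    "ILE": {"CD1"}, "LEU": {"CD1", "CD2"}, "LYS": {"NZ"},
    "MET": {"CE"}, "PHE": {"CZ"}, "PRO": {"CG"}, "SER": {"OG"},
    "THR": {"OG1"}, "TRP": {"NE1", "CZ2", "CH2"}, "TYR": {"OH"},
    "VAL": {"CG1", "CG2"},
}
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def membrane_depth_profile(
    struct: Structure,
    leaflet_planes: tuple[float, float],
    residues=None,
    axis: AxisFrame | None = None,
    interface_halfwidth: float = 2.0,
):
    """Signed membrane depth per residue relative to the nearest leaflet
    plane (axial coordinates).

    Depth is the mean axial coordinate of the residue's side-chain
    terminal atoms minus the nearest leaflet plane, signed so that
    negative means buried toward the bilayer midplane.  Classification:
    ``interfacial`` if |depth| < interface_halfwidth, else ``embedded``
    (negative) or ``solvent`` (positive).  Returns a pandas DataFrame.
    """
    import pandas as pd

    z_lower, z_upper = leaflet_planes
    if not z_lower < z_upper:
        raise ValueError("require z_lower < z_upper")
    if residues is not None:
        wanted = set(residues)
        atoms = [a for a in struct.atoms if a.residue_id in wanted
                 or (a.chain_id, a.resseq) in wanted or a.resseq in wanted]
        if not atoms:
            raise ValueError("residue selection matches nothing")
    else:
        atoms = struct.atoms
    get_z = ((lambda a: float(axis.to_axis(a.xyz)[0, 2])) if axis is not None
             else (lambda a: float(a.xyz[2])))

    by_res: dict[tuple, list[AtomRecord]] = {}
    for a in atoms:
        by_res.setdefault(a.residue_id, []).append(a)
    rows = []
    for rid, ratoms in by_res.items():
        terminals = _TERMINAL_ATOMS.get(rid[1])
        if terminals is not None:
            chosen = [a for a in ratoms if a.name in terminals]
        else:
            chosen = [a for a in ratoms if a.name not in _BACKBONE]
        if not chosen:
            chosen = ratoms
        zbar = float(np.mean([get_z(a) for a in chosen]))
        d_upper = zbar - z_upper
        d_lower = z_lower - zbar
        depth = d_upper if abs(d_upper) <= abs(d_lower) else d_lower
        if abs(depth) < interface_halfwidth:
            cls = "interfacial"
        elif depth < 0:
            cls = "embedded"
        else:
            cls = "solvent"
        rows.append({"chain": rid[0], "resname": rid[1], "resseq": rid[2],
                     "icode": rid[3], "depth": depth, "class": cls})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SuperpositionResult:
    rmsd: float
    rotation: np.ndarray       # 3x3, proper
    translation: np.ndarray    # maps B onto A: x_A ~ R x_B + t
    n_atoms: int


def _match_atoms(A: Structure, B: Structure, selection):
    def keep(a: AtomRecord) -> bool:
        if selection is None:
            return True
        if callable(selection):
            return bool(selection(a))
        return a.name in selection
    key = lambda a: (a.chain_id, a.resseq, a.icode, a.name)
    map_a = {key(a): a for a in A.atoms if keep(a)}
    map_b = {key(b): b for b in B.atoms if keep(b)}
    if set(map_a) != set(map_b):
        missing = sorted(set(map_a) ^ set(map_b))[0]
        raise ValueError(
            f"selections do not correspond 1:1; first mismatch: {missing}")
    keys = sorted(map_a)
    xa = np.array([map_a[k].xyz for k in keys])
    xb = np.array([map_b[k].xyz for k in keys])
    return xa, xb


def superpose_rmsd(A: Structure, B: Structure, selection=None) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch, proper rotation) of B
    onto A over atoms matched by (chain, resseq, icode, name).

    ``selection`` is None (all atoms), a set of atom names (e.g. {"CA"}
    for C-alpha RMSD), or a predicate on AtomRecord.
    """
    xa, xb = _match_atoms(A, B, selection)
    if len(xa) < 3:
        raise ValueError("need at least 3 matched atoms")
    ca, cb = xa.mean(axis=0), xb.mean(axis=0)
    if np.linalg.matrix_rank(xa - ca, tol=1e-8) < 2:
        raise ValueError("matched atoms are collinear")
    rot, rssd = Rotation.align_vectors(xa - ca, xb - cb)
    R = rot.as_matrix()
    rmsd = float(rssd) / math.sqrt(len(xa))
    return SuperpositionResult(
        rmsd=rmsd, rotation=R, translation=ca - R @ cb, n_atoms=len(xa))
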