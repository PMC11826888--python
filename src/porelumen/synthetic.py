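"""Synthetic ground-truth generators.

Three generators provide analytically known inputs for every analysis
stage:

* :func:`make_barrel` — a Cn-symmetric bead model of a beta-barrel with
  designed constriction rings, emulating a heptameric 14-stranded pore
  (seven protomers, two antiparallel strands each, ~120 A long).
* :func:`make_ion_trajectory` — a drift-diffusion electrolyte: charged
  Gaussian walkers under a uniform axial field, whose expected ionic
  current follows in closed form from the Einstein relation.
* :func:`make_pore_water_trajectory` — water points resampled uniformly
  inside a tube of known radius profile, bounded by a static bead wall,
  the ground truth for the water-accessibility-radius algorithm.

All generators are pure functions of their spec and seed.  The walkers
carry statistical structure only (independent steps, i.i.d. water
resampling); they model no physical interactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB_EV
from .io import AtomRecord, BoxDims, Frame, Structure, Topology, Trajectory

__all__ = [
    "BarrelSpec", "IonWalkSpec", "make_barrel", "make_ion_trajectory",
    "make_pore_water_trajectory", "wt_barrel_spec", "k238a_barrel_spec",
    "radius_profile_function",
]

#: protomer chain identifiers, in Cn order
_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class BarrelSpec:
    """Geometry of a synthetic Cn-symmetric bead barrel.

    ``constrictions`` is a list of (z_center A, target_radius A,
    axial_width A) triples; the lumen radius profile is the pointwise
    minimum of Gaussian wells of the given width dug into ``base_radius``,
    reaching exactly ``target_radius`` at each center.
    """

    n_protomers: int = 7
    strands_per_protomer: int = 2
    length: float = 120.0
    base_radius: float = 8.5
    constrictions: tuple[tuple[float, float, float], ...] = ()
    bead_spacing: float = 1.5
    bead_vdw: float = 1.7
    seed: int = 0

    def __post_init__(self):
        for (zc, r, w) in self.constrictions:
            if not (0.0 <= zc <= self.length):
                raise ValueError(f"constriction center {zc} outside [0, length]")
            if not r < self.base_radius:
                raise ValueError("target_radius must be < base_radius")
            if w <= 0:
                raise ValueError("axial_width must be positive")
        if self.n_protomers < 1 or self.strands_per_protomer < 1:
            raise ValueError("need at least one protomer and one strand")


def radius_profile_function(spec: BarrelSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Designed lumen radius r(z) of a barrel spec (vectorized in z)."""

    def profile(z):
        z = np.asarray(z, dtype=float)
        r = np.full(z.shape, spec.base_radius)
        for (zc, target, width) in spec.constrictions:
            sigma = width / 2.0
            well = spec.base_radius - (spec.base_radius - target) * np.exp(
                -((z - zc) ** 2) / (2.0 * sigma ** 2))
            r = np.minimum(r, well)
        return r

    return profile


# The four-ring wild-type layout: two rings near the extracellular end
# (the R282 and R220 positions) and two near the cytoplasmic end (K238
# and the K242/K244 pair), 5 A rings in an 8.5 A cavity.
_WT_RINGS = ((12.0, 5.0, 8.0), (26.0, 5.0, 8.0),
             (94.0, 5.0, 8.0), (108.0, 5.0, 8.0))


def wt_barrel_spec(**overrides) -> BarrelSpec:
    """Wild-type-emulating spec: four 5 A constriction rings, two per end."""
    kwargs = dict(constrictions=_WT_RINGS)
    kwargs.update(overrides)
    return BarrelSpec(**kwargs)


def k238a_barrel_spec(widened_radius: float = 7.0, **overrides) -> BarrelSpec:
    """K238A-emulating spec: only the third ring widened, others unchanged."""
    rings = list(_WT_RINGS)
    zc, _, w = rings[2]
    rings[2] = (zc, widened_radius, w)
    kwargs = dict(constrictions=tuple(rings))
    kwargs.update(overrides)
    return BarrelSpec(**kwargs)


def make_barrel(spec: BarrelSpec) -> Structure:
    """Build the bead barrel: beads on vertical strand lines at radial
    distance ``r(z) + bead_vdw``, replicated by n-fold rotation about z.

    Chain ids label protomers; within a protomer the two strands share
    residue numbering (resseq = bead index along the strand, 1-based) and
    differ in atom name (C1, C2, ...), so a constriction's lining
    deduplicates to one residue per protomer.
    """
    profile = radius_profile_function(spec)
    n_beads = int(math.floor(spec.length / spec.bead_spacing)) + 1
    z_beads = np.arange(n_beads) * spec.bead_spacing
    wall = profile(z_beads) + spec.bead_vdw
    if np.any(profile(z_beads) <= 0):
        raise ValueError("spec yields non-positive lumen radius")
    n_strands = spec.n_protomers * spec.strands_per_protomer
    atoms: list[AtomRecord] = []
    serial = 1
    for p in range(spec.n_protomers):
        chain = _CHAIN_IDS[p % len(_CHAIN_IDS)]
        for s in range(spec.strands_per_protomer):
            theta = 2.0 * math.pi * (p * spec.strands_per_protomer + s) / n_strands
            for k in range(n_beads):
                r = wall[k]
                atoms.append(AtomRecord(
                    serial=serial,
                    name=f"C{s + 1}",
                    element="C",
                    resname="BRL",
                    chain_id=chain,
                    resseq=k + 1,
                    icode="",
                    altloc="",
                    xyz=np.array([r * math.cos(theta),
                                  r * math.sin(theta),
                                  z_beads[k]]),
                    occupancy=1.0,
                    vdw_radius=spec.bead_vdw,
                ))
                serial += 1
    return Structure(atoms, symmetry_hint=spec.n_protomers)


# ---------------------------------------------------------------------------
# electrolyte walkers

@dataclass(frozen=True)
class IonWalkSpec:
    """Drift-diffusion electrolyte under a uniform axial field.

    Each ion takes independent Gaussian steps of variance 2*D*dt per axis
    plus an axial drift q*E_z*D/(k_B*T)*dt (Einstein relation; sign set by
    the charge).  D in A^2/ps, E_z in V/A, dt in ps.
    """

    n_cation: int = 10
    n_anion: int = 10
    q_cation: float = 1.0
    q_anion: float = -1.0
    D: float = 0.2
    E_z: float = 0.0
    T: float = DEFAULT_TEMPERATURE
    dt: float = 10.0
    n_frames: int = 1000
    box: BoxDims = field(default_factory=lambda: BoxDims(40.0, 40.0, 80.0))
    seed: int = 0

    def __post_init__(self):
        if not (self.D > 0 and self.dt > 0 and self.n_frames >= 2):
            raise ValueError("require D > 0, dt > 0, n_frames >= 2")

    def drift_per_step(self, q: float) -> float:
        """Axial drift per frame (A) for an ion of charge q (e)."""
        return q * self.E_z * self.D / (KB_EV * self.T) * self.dt

    @property
    def expected_current(self) -> float:
        """Ground-truth mean current (e/ps)."""
        mu_cat = self.drift_per_step(self.q_cation)
        mu_an = self.drift_per_step(self.q_anion)
        return (self.n_cation * self.q_cation * mu_cat
                + self.n_anion * self.q_anion * mu_an) / (self.box.Lz * self.dt)


def make_ion_trajectory(spec: IonWalkSpec) -> Trajectory:
    """Generate the walker trajectory; the analytic expected current is
    attached as ``traj.meta["expected_current_e_ps"]``."""
    for q in (spec.q_cation, spec.q_anion):
        if abs(spec.drift_per_step(q)) > spec.box.Lz / 4.0:
            raise ValueError("drift per step exceeds L_z/4; unwrapping ambiguous")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cation + spec.n_anion
    charges = np.concatenate([
        np.full(spec.n_cation, spec.q_cation),
        np.full(spec.n_anion, spec.q_anion)])
    names = ["CAT"] * spec.n_cation + ["ANI"] * spec.n_anion
    L = spec.box.lengths
    pos = rng.uniform(0.0, 1.0, size=(n, 3)) * L
    sigma = math.sqrt(2.0 * spec.D * spec.dt)
    drift = np.array([spec.drift_per_step(q) for q in charges])
    frames = [Frame(time=0.0, box=spec.box, coords=pos.copy())]
    for k in range(1, spec.n_frames):
        step = rng.normal(0.0, sigma, size=(n, 3))
        step[:, 2] += drift
        pos = np.mod(pos + step, L)
        frames.append(Frame(time=k * spec.dt, box=spec.box, coords=pos.copy()))
    traj = Trajectory(Topology(names, charges), frames)
    traj.meta["expected_current_e_ps"] = spec.expected_current
    traj.meta["spec"] = spec
    return traj


# ---------------------------------------------------------------------------
# confined water

def make_pore_water_trajectory(
    radius_true,
    length: float = 120.0,
    n_water: int = 2000,
    n_frames: int = 100,
    seed: int = 0,
    box_pad: float = 12.0,
    wall_offset: float = 0.3,
    wall_spacing: float = 1.0,
    dt: float = 1.0,
    on_axis: bool = False,
) -> tuple[Trajectory, Structure]:
    """Water points uniformly resampled each frame inside ``r < R(z)``,
    plus a static bead wall just outside the tube.

    ``radius_true`` is either a scalar (constant radius) or a callable
    z -> radius (A), defined on [0, length].  The returned trajectory
    contains the waters (names ``OW``) followed by the static wall beads
    (names ``WAL``); the wall is also returned as a Structure.  The tube
    axis runs along z through the box center in x/y.  ``on_axis`` collapses
    every water onto the axis (zero-variance override for degenerate tests).
    """
    if n_water < 1:
        raise ValueError("n_water must be >= 1")
    R = radius_true if callable(radius_true) else (
        lambda z, _r=float(radius_true): np.full(np.shape(z), _r))
    zs = np.linspace(0.0, length, 512)
    rmaxs = np.asarray(R(zs), dtype=float)
    if not np.all(rmaxs > 0):
        raise ValueError("radius_true must be positive over the pore span")
    r_extent = float(rmaxs.max()) + wall_offset
    Lxy = 2.0 * (r_extent + box_pad)
    box = BoxDims(Lxy, Lxy, length)
    cx = cy = Lxy / 2.0

    # wall: rings of beads at R(z) + wall_offset, arc spacing ~ wall_spacing
    wall_atoms: list[AtomRecord] = []
    serial = 1
    z_rings = np.arange(0.0, length + 1e-9, wall_spacing)
    for resseq, z in enumerate(z_rings, start=1):
        rw = float(R(z)) + wall_offset
        n_phi = max(8, int(math.ceil(2.0 * math.pi * rw / wall_spacing)))
        for j in range(n_phi):
            phi = 2.0 * math.pi * j / n_phi
            wall_atoms.append(AtomRecord(
                serial=serial, name=f"W{j + 1}", element="C", resname="WAL",
                chain_id="W", resseq=resseq, icode="", altloc="",
                xyz=np.array([cx + rw * math.cos(phi),
                              cy + rw * math.sin(phi), z]),
                occupancy=1.0, vdw_radius=1.7))
            serial += 1
    wall = Structure(wall_atoms)
    wall_xyz = wall.coords

    rng = np.random.default_rng(seed)
    frames = []
    for k in range(n_frames):
        z = rng.uniform(0.0, length, size=n_water)
        if on_axis:
            x = np.full(n_water, cx)
            y = np.full(n_water, cy)
        else:
            rr = np.asarray(R(z), float) * np.sqrt(rng.uniform(size=n_water))
            phi = rng.uniform(0.0, 2.0 * math.pi, size=n_water)
            x = cx + rr * np.cos(phi)
            y = cy + rr * np.sin(phi)
        coords = np.concatenate([np.column_stack([x, y, z]), wall_xyz])
        frames.append(Frame(time=k * dt, box=box, coords=coords))

    names = ["OW"] * n_water + ["WAL"] * len(wall_atoms)
    charges = np.zeros(n_water + len(wall_atoms))
    traj = Trajectory(Topology(names, charges), frames)
    traj.meta["axis_center_xy"] = (cx, cy)
    traj.meta["radius_true"] = R
    return traj, wall
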