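"""Water-accessibility radius from trajectory density maps.

The algorithm: (1) average water and pore-atom occupancies over the
trajectory on a 3D voxel grid spanning the box; (2) at each position z
along the pore axis, average each density over thin annuli of width dr
centered on the axis; (3) scan r outward from the axis and, at the first
annulus where the water/pore density ratio drops below a threshold,
report the previous annulus' outer edge as the water-accessibility
radius at that z.

Scan semantics: the lumen is water-rich and essentially protein-free, so
the ratio starts far above the threshold and the *downward* crossing on
the way out marks the wall.  If the ratio never crosses, the radius is
capped at r_max; if there is no water in the innermost annulus, the
radius is undefined at that z.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import AxisFrame
from .io import Structure, Trajectory

__all__ = [
    "DensityGrid", "RingDensityProfile", "WaterRadiusProfile",
    "density_grid", "density_grid_from_structure", "ring_average",
    "water_accessibility_radius", "resolve_selection",
]

#: density floor guarding the water/pore ratio against division by zero
EPSILON_DENSITY = 1e-6


@dataclass
class DensityGrid:
    """Mean per-frame occupancy density on a regular voxel grid (A^-3)."""

    origin: np.ndarray         # (3,)
    spacing: np.ndarray        # (3,) voxel edge lengths, A
    counts: np.ndarray         # (nx, ny, nz), >= 0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.spacing = np.asarray(self.spacing, float)
        self.counts = np.asarray(self.counts, float)
        if np.any(self.counts < 0):
            raise ValueError("densities must be non-negative")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def integral(self) -> float:
        """Total density integral = mean selected-atom count per frame."""
        return float(self.counts.sum() * self.voxel_volume)

    def voxel_centers(self):
        """1D center coordinate arrays (x, y, z)."""
        return tuple(
            self.origin[k] + (np.arange(self.counts.shape[k]) + 0.5)
            * self.spacing[k]
            for k in range(3))

    def commensurate_with(self, other: "DensityGrid") -> bool:
        return (self.counts.shape == other.counts.shape
                and np.allclose(self.origin, other.origin)
                and np.allclose(self.spacing, other.spacing))


def resolve_selection(traj: Trajectory, selection) -> np.ndarray:
    """Resolve a selection to atom indices.

    ``selection`` may be: a string (matched against topology names),
    a sequence of indices, a boolean mask, or a predicate on the name.
    """
    names = traj.topology.names
    if isinstance(selection, str):
        idx = np.flatnonzero([n == selection for n in names])
    elif callable(selection):
        idx = np.flatnonzero([bool(selection(n)) for n in names])
    else:
        arr = np.asarray(selection)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            idx = arr.astype(int)
    if len(idx) == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    return idx


def density_grid(traj: Trajectory, selection, spacing: float = 1.0) -> DensityGrid:
    """Trajectory-averaged density map of the selected atoms over the box.

    The box is tiled by ``ceil(L/spacing)`` voxels per axis (actual voxel
    edges are L/n so the grid spans the box exactly); per-frame counts are
    averaged over frames and normalized by voxel volume.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    idx = resolve_selection(traj, selection)
    L = traj.box.lengths
    nbins = np.maximum(1, np.ceil(L / spacing).astype(int))
    edges = [np.linspace(0.0, L[k], nbins[k] + 1) for k in range(3)]
    acc = np.zeros(tuple(nbins))
    for f in traj.frames:
        h, _ = np.histogramdd(f.coords[idx], bins=edges)
        acc += h
    acc /= traj.n_frames
    voxel = L / nbins
    return DensityGrid(origin=np.zeros(3), spacing=voxel,
                       counts=acc / np.prod(voxel))


def density_grid_from_structure(struct: Structure, box_lengths,
                                spacing: float = 1.0) -> DensityGrid:
    """Static density map of a structure (a single implicit frame)."""
    L = np.asarray(box_lengths, float)
    nbins = np.maximum(1, np.ceil(L / spacing).astype(int))
    edges = [np.linspace(0.0, L[k], nbins[k] + 1) for k in range(3)]
    h, _ = np.histogramdd(np.mod(struct.coords, L), bins=edges)
    voxel = L / nbins
    return DensityGrid(origin=np.zeros(3), spacing=voxel,
                       counts=h / np.prod(voxel))


@dataclass
class RingDensityProfile:
    """Annulus-averaged density about the pore axis at one z position."""

    r: np.ndarray              # bin centers, uniform, first bin starts at 0
    dr: float
    density: np.ndarray        # mean density per annulus; NaN where empty

    @property
    def outer_edges(self) -> np.ndarray:
        return self.r + self.dr / 2.0


def ring_average(grid: DensityGrid, axis: AxisFrame, z: float,
                 dz: float = 1.0, dr: float = 0.5,
                 r_max: float = 15.0) -> RingDensityProfile:
    """Mean density in annuli [r, r+dr) about the axis, over the axial
    slab [z - dz/2, z + dz/2).  Annuli containing no voxel are NaN."""
    xc, yc, zc = grid.voxel_centers()
    X, Y, Z = np.meshgrid(xc, yc, zc, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    uvz = axis.to_axis(pts)
    zax = uvz[:, 2]
    in_slab = (zax >= z - dz / 2.0) & (zax < z + dz / 2.0)
    if not np.any(in_slab):
        raise ValueError(f"no voxels in slab at z={z}")
    rad = np.hypot(uvz[in_slab, 0], uvz[in_slab, 1])
    vals = grid.counts.ravel()[in_slab]
    nbins = int(np.ceil(r_max / dr))
    which = np.floor(rad / dr).astype(int)
    keep = which < nbins
    sums = np.bincount(which[keep], weights=vals[keep], minlength=nbins)
    cnts = np.bincount(which[keep], minlength=nbins)
    with np.errstate(invalid="ignore"):
        mean = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    centers = (np.arange(nbins) + 0.5) * dr
    return RingDensityProfile(r=centers, dr=dr, density=mean)


@dataclass
class WaterRadiusProfile:
    """Water-accessibility radius per axial grid point.

    ``flag``: ``open`` (crossing found), ``capped`` (ratio never dropped
    below threshold within r_max), ``undefined`` (no water on the axis —
    outside the pore span).  Radii are NaN where undefined.
    """

    z: np.ndarray
    radius: np.ndarray
    flag: np.ndarray
    threshold_used: float

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({"z": self.z, "radius": self.radius,
                             "flag": self.flag})


def water_accessibility_radius(
    water: DensityGrid,
    pore: DensityGrid,
    axis: AxisFrame,
    z_grid: Sequence[float],
    dz: float = 1.0,
    dr: float = 0.5,
    r_max: float = 15.0,
    threshold: float = 1.0,
    eps: float = EPSILON_DENSITY,
) -> WaterRadiusProfile:
    """Threshold-ratio radius scan on water and pore density maps.

    At each z the water/pore density ratio is scanned outward from the
    axis; while it stays >= ``threshold`` the scan continues, and at the
    first annulus where it drops below, the previous annulus' outer edge
    is the radius.  See the module docstring for the limit conventions.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not water.commensurate_with(pore):
        raise ValueError("water and pore grids are not commensurate")
    z_grid = np.asarray(z_grid, float)
    radius = np.full(len(z_grid), np.nan)
    flags = np.empty(len(z_grid), dtype=object)
    for i, z in enumerate(z_grid):
        wprof = ring_average(water, axis, z, dz=dz, dr=dr, r_max=r_max)
        pprof = ring_average(pore, axis, z, dz=dz, dr=dr, r_max=r_max)
        w, p = wprof.density, pprof.density
        # annuli without any voxel center carry no evidence; skip them
        # (the voxel pattern is geometric, hence identical for both grids)
        have = ~np.isnan(w)
        if not np.any(have) or w[have][0] <= 0.0:
            flags[i] = "undefined"
            continue
        flags[i] = "capped"
        radius[i] = r_max
        for k in np.flatnonzero(have):
            ratio = w[k] / max(p[k] if not np.isnan(p[k]) else 0.0, eps)
            if ratio < threshold:
                radius[i] = k * dr      # previous annulus' outer edge
                flags[i] = "open"
                break
    return WaterRadiusProfile(z=z_grid, radius=radius,
                              flag=flags.astype(str), threshold_used=threshold)
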