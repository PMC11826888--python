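"""Ionic current from trajectories, I-V curves, and bulk conductivity.

The instantaneous current between consecutive frames is

    I(t) = 1/(L_z * dt) * sum_i q_i * dz_i

with q_i the ion charge (e), dz_i the axial displacement over the frame
interval, L_z the box length along the pore axis and dt the frame
spacing.  Periodic boundary crossings are unwrapped per transition by the
minimum-image rule, mapping each raw displacement into (-L_z/2, +L_z/2];
generators and typical MD output satisfy step << L_z/2 so the unwrapping
is unambiguous.  Currents are kept in e/ps internally and converted to pA
(1 e/ps = 1.602176634e5 pA) only when reported.

Sign convention: positive voltage applies a uniform field E_z = V/L_z
along +z and drives cations toward +z, yielding positive current.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import E_PER_PS_TO_PA, SIGMA_INTERNAL_TO_MS_PER_CM
from .io import BoxDims, Frame, Trajectory

__all__ = [
    "CurrentSeries", "IVPoint", "ConductivityResult",
    "frame_current", "current_series", "mean_current", "iv_curve",
    "rectification_ratios", "bulk_conductivity", "relative_deviation",
]


def _min_image(dz: np.ndarray, L: float) -> np.ndarray:
    """Map displacements into the half-open interval (-L/2, +L/2]."""
    out = np.mod(dz, L)
    out = np.where(out > L / 2.0, out - L, out)
    return out


@dataclass
class CurrentSeries:
    """Per-transition currents; length is n_frames - 1."""

    t: np.ndarray              # transition midpoint times, ps
    I: np.ndarray              # e/ps
    L_z: float
    dt: float

    @property
    def I_pA(self) -> np.ndarray:
        return self.I * E_PER_PS_TO_PA


def frame_current(frame_a: Frame, frame_b: Frame, charges: np.ndarray,
                  ion_selection=None) -> float:
    """Current (e/ps) for a single consecutive-frame transition."""
    if frame_a.coords.shape != frame_b.coords.shape:
        raise ValueError("frames have mismatched topology")
    dt = frame_b.time - frame_a.time
    if dt <= 0:
        raise ValueError("frames must be consecutive in time")
    L_z = frame_a.box.Lz
    charges = np.asarray(charges, float)
    idx = (np.arange(len(charges)) if ion_selection is None
           else np.asarray(ion_selection, int))
    dz = _min_image(frame_b.coords[idx, 2] - frame_a.coords[idx, 2], L_z)
    return float(np.sum(charges[idx] * dz) / (L_z * dt))


def current_series(traj: Trajectory, charges: np.ndarray | None = None,
                   ion_selection=None) -> CurrentSeries:
    """Vectorized per-transition currents over a whole trajectory."""
    q = (traj.topology.charges if charges is None
         else np.asarray(charges, float))
    coords = traj.coords_array()
    if ion_selection is not None:
        sel = np.asarray(ion_selection, int)
        coords = coords[:, sel, :]
        q = q[sel]
    L_z = traj.box.Lz
    dt = traj.dt
    dz = _min_image(np.diff(coords[:, :, 2], axis=0), L_z)
    I = (dz * q).sum(axis=1) / (L_z * dt)
    times = np.array([f.time for f in traj.frames])
    return CurrentSeries(t=0.5 * (times[:-1] + times[1:]), I=I,
                         L_z=L_z, dt=dt)


def mean_current(traj: Trajectory, charges: np.ndarray | None = None,
                 ion_selection=None, n_blocks: int = 5) -> tuple[float, float]:
    """Trajectory-mean current in pA with a block-averaged SEM.

    The SEM is the standard deviation of ``n_blocks`` contiguous block
    means divided by sqrt(n_blocks); with n_blocks < 2 the SEM is
    returned as NaN (undefined).
    """
    series = current_series(traj, charges, ion_selection)
    n = len(series.I)
    if n < n_blocks:
        raise ValueError(f"need at least n_blocks={n_blocks} transitions")
    mean = float(series.I.mean()) * E_PER_PS_TO_PA
    if n_blocks < 2:
        return mean, float("nan")
    blocks = np.array_split(series.I, n_blocks)
    bmeans = np.array([b.mean() for b in blocks])
    sem = float(bmeans.std(ddof=1) / np.sqrt(n_blocks)) * E_PER_PS_TO_PA
    return mean, sem


@dataclass(frozen=True)
class IVPoint:
    voltage: float             # mV
    mean_current: float        # pA
    sem: float                 # pA
    n_blocks: int


def iv_curve(runs: Sequence[tuple[float, Trajectory, np.ndarray | None]],
             n_blocks: int = 5) -> list[IVPoint]:
    """One IVPoint per (voltage mV, trajectory, charges) run, sorted by
    voltage.  Duplicate voltages are rejected."""
    if not runs:
        raise ValueError("need at least one run")
    voltages = [v for v, _, _ in runs]
    if len(set(voltages)) != len(voltages):
        raise ValueError("duplicate voltages in I-V runs")
    points = []
    for v, traj, q in sorted(runs, key=lambda r: r[0]):
        m, s = mean_current(traj, q, n_blocks=n_blocks)
        points.append(IVPoint(voltage=float(v), mean_current=m, sem=s,
                              n_blocks=n_blocks))
    return points


def rectification_ratios(points: Sequence[IVPoint]) -> dict[float, float]:
    """|I(+V)| / |I(-V)| for each matched +/-V pair, keyed by |V|."""
    by_v = {p.voltage: p for p in points}
    out = {}
    for v, p in by_v.items():
        if v > 0 and -v in by_v and by_v[-v].mean_current != 0:
            out[v] = abs(p.mean_current) / abs(by_v[-v].mean_current)
    return out


@dataclass(frozen=True)
class ConductivityResult:
    sigma: float               # mS/cm
    mean_current: float        # pA
    sem: float                 # pA
    voltage: float             # mV
    box: BoxDims


def bulk_conductivity(traj: Trajectory, charges: np.ndarray | None,
                      voltage: float, box: BoxDims | None = None,
                      n_blocks: int = 5) -> ConductivityResult:
    """Bulk conductivity of a homogeneous electrolyte trajectory under a
    uniform axial field E_z = voltage / L_z.

    sigma = <I> / (E_z * Lx * Ly), reported in mS/cm.
    """
    if voltage == 0:
        raise ValueError("conductivity undefined at zero voltage")
    box = box or traj.box
    mean_pA, sem_pA = mean_current(traj, charges, n_blocks=n_blocks)
    E_z = (voltage * 1e-3) / box.Lz               # V/A
    sigma_internal = (mean_pA / E_PER_PS_TO_PA) / (E_z * box.area_xy)
    return ConductivityResult(
        sigma=sigma_internal * SIGMA_INTERNAL_TO_MS_PER_CM,
        mean_current=mean_pA, sem=sem_pA, voltage=float(voltage), box=box)


def relative_deviation(value_sim: float, value_ref: float) -> float:
    """100 * |sim - ref| / |ref|, rounded to one decimal (percent)."""
    if value_ref == 0:
        raise ValueError("reference value must be nonzero")
    return round(100.0 * abs(value_sim - value_ref) / abs(value_ref), 1)
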