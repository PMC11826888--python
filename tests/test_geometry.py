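import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import porelumen as pl
from porelumen.geometry import AxisFrame, ConstrictionRing, PoreProfile


def _rotation(seed=0):
    return Rotation.random(random_state=np.random.default_rng(seed)).as_matrix()


def _kabsch_oracle(xa, xb):
    """Plain SVD Kabsch, independent of the implementation under test."""
    ca, cb = xa.mean(0), xb.mean(0)
    H = (xb - cb).T @ (xa - ca)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    diff = (xa - ca) - (xb - cb) @ R.T
    return math.sqrt((diff ** 2).sum() / len(xa))


class TestPrincipalAxis:
    def test_barrel_axis_is_z(self, wt_barrel):
        axis = pl.principal_pore_axis(wt_barrel)
        assert np.allclose(axis.direction, [0, 0, 1], atol=1e-6)

    def test_rotated_barrel(self, wt_barrel):
        R = _rotation(1)
        rotated = wt_barrel.transformed(R, np.array([5.0, -3.0, 2.0]))
        axis = pl.principal_pore_axis(rotated)
        expected = R @ np.array([0.0, 0.0, 1.0])
        agree = min(np.linalg.norm(axis.direction - expected),
                    np.linalg.norm(axis.direction + expected))
        assert agree < 1e-6

    def test_tetrahedron_is_degenerate(self):
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float)
        atoms = [replace(a, xyz=p, serial=i + 1, resseq=i + 1)
                 for i, (a, p) in enumerate(
                     zip([pl.make_barrel(pl.BarrelSpec()).atoms[0]] * 4, pts))]
        s = pl.Structure(atoms)
        with pytest.raises(ValueError, match="degenerate"):
            pl.principal_pore_axis(s)


class TestRadiusProfile:
    def test_monotone_under_atom_addition(self, plain_cylinder):
        axis = AxisFrame.along_z()
        prof = pl.radius_profile(plain_cylinder, axis, dz=2.0)
        extra = replace(plain_cylinder.atoms[0], xyz=np.array([2.0, 0.0, 20.0]),
                        chain_id="Z", serial=99999)
        bigger = pl.Structure(plain_cylinder.atoms + [extra])
        prof2 = pl.radius_profile(bigger, axis, dz=2.0)
        assert np.all(prof2.radius <= prof.radius + 1e-9)
        i20 = np.argmin(np.abs(prof.z - 20.0))
        assert prof2.radius[i20] < prof.radius[i20] - 0.5

    def test_optimized_at_least_axial(self, wt_barrel, wt_axis):
        opt = pl.radius_profile(wt_barrel, wt_axis, dz=2.0, mode="optimized")
        axial = pl.radius_profile(wt_barrel, wt_axis, dz=2.0, mode="axial")
        assert np.all(opt.radius >= axial.radius - 1e-9)

    def test_optimized_matches_brute_force_grid(self):
        """Deterministic grid+simplex vs 0.05 A exhaustive in-plane search."""
        spec = pl.BarrelSpec(length=28.0, bead_spacing=2.0,
                             constrictions=((14.0, 5.0, 6.0),))
        barrel = pl.make_barrel(spec)
        assert abs(len(barrel) - 200) < 20
        axis = AxisFrame.along_z(barrel.coords.mean(axis=0))
        prof = pl.radius_profile(barrel, axis, dz=1.5, center_bound=3.0)
        uvz = axis.to_axis(barrel.coords)
        ticks = np.arange(-3.0, 3.0001, 0.05)
        gu, gv = np.meshgrid(ticks, ticks)
        centers = np.column_stack([gu.ravel(), gv.ravel()])
        centers = centers[(centers ** 2).sum(1) <= 9.0]
        for z, r, flag in zip(prof.z, prof.radius, prof.flag):
            if flag != "open":
                continue
            dist = np.sqrt(
                ((centers[:, None, :] - uvz[None, :, :2]) ** 2).sum(-1)
                + (uvz[:, 2] - z) ** 2)
            brute = (dist - barrel.vdw).min(axis=1).max()
            assert abs(r - brute) < 0.05

    def test_rigid_invariance(self, plain_cylinder):
        axis = AxisFrame.along_z()
        prof = pl.radius_profile(plain_cylinder, axis, dz=4.0)
        R, t = _rotation(2), np.array([3.0, 4.0, -5.0])
        moved = plain_cylinder.transformed(R, t)
        maxis = AxisFrame(R @ axis.origin + t, R @ axis.direction)
        prof2 = pl.radius_profile(moved, maxis, dz=4.0)
        assert np.allclose(prof.radius, prof2.radius, atol=1e-5)

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            pl.Structure([])


class TestConstrictions:
    def test_monotone_profile_has_no_rings(self):
        z = np.arange(0.0, 20.0, 1.0)
        prof = PoreProfile(z, np.linspace(3.0, 9.0, len(z)),
                           np.zeros((len(z), 2)),
                           np.array(["open"] * len(z)))
        assert pl.detect_constrictions(prof) == []

    def test_four_rings_at_designed_positions(self, wt_profile):
        rings = pl.detect_constrictions(wt_profile)
        assert len(rings) == 4
        spec = pl.wt_barrel_spec()
        origin_z = spec.length / 2.0      # axis origin is the centroid
        designed = sorted(zc - origin_z for zc, _, _ in spec.constrictions)
        for ring, zd in zip(rings, designed):
            assert abs(ring.z_min - zd) <= wt_profile.dz
            assert abs(ring.radius_min - 5.0) <= 0.3

    def test_close_minima_merged_keeping_deeper(self):
        z = np.arange(0.0, 20.0, 1.0)
        r = np.full(len(z), 9.0)
        r[8], r[10] = 5.0, 4.0            # minima 2 A apart
        prof = PoreProfile(z, r, np.zeros((len(z), 2)),
                           np.array(["open"] * len(z)))
        rings = pl.detect_constrictions(prof, merge_window=5.0)
        assert len(rings) == 1
        assert rings[0].radius_min == pytest.approx(4.0)

    def test_no_open_region_gives_empty_list(self):
        z = np.arange(0.0, 5.0, 1.0)
        prof = PoreProfile(z, np.full(len(z), -1.0), np.zeros((len(z), 2)),
                           np.array(["blocked"] * len(z)))
        assert pl.detect_constrictions(prof) == []


class TestLiningResidues:
    def test_one_residue_per_protomer(self, wt_barrel, wt_axis, wt_profile):
        spec = pl.wt_barrel_spec()
        rings = pl.detect_constrictions(wt_profile)
        for ring, (zc, _, _) in zip(rings, spec.constrictions):
            lining = pl.lining_residues(wt_barrel, wt_axis, ring)
            assert len(lining) == 7
            assert {r[0] for r in lining} == set("ABCDEFG")
            # the labeled bead: resseq of the bead nearest the designed z
            expected_resseq = round(zc / spec.bead_spacing) + 1
            assert {r[2] for r in lining} == {expected_resseq}

    def test_zero_slab_is_empty(self, wt_barrel, wt_axis, wt_profile):
        ring = pl.detect_constrictions(wt_profile)[0]
        off_grid = ConstrictionRing(ring.z_min + 0.123, ring.radius_min,
                                    ring.prominence)
        assert pl.lining_residues(wt_barrel, wt_axis, off_grid,
                                  slab_halfwidth=0.0) == []

    def test_n_nearest_saturates(self, wt_barrel, wt_axis, wt_profile):
        ring = pl.detect_constrictions(wt_profile)[0]
        all_res = pl.lining_residues(wt_barrel, wt_axis, ring,
                                     slab_halfwidth=1.0, n_nearest=10 ** 6)
        in_slab = {a.residue_id for a in wt_barrel.atoms
                   if abs(a.xyz[2] - (ring.z_min + 60.0)) <= 1.0}
        assert set(all_res) == in_slab


class TestMembraneDepth:
    @staticmethod
    def _bead(z, resseq, name="NZ", resname="LYS"):
        return pl.AtomRecord(serial=resseq, name=name, element="N",
                             resname=resname, chain_id="A", resseq=resseq,
                             icode="", altloc="", xyz=np.array([0.0, 0.0, z]),
                             occupancy=1.0, vdw_radius=1.55)

    def test_midplane_is_embedded(self):
        s = pl.Structure([self._bead(0.0, 1)])
        df = pl.membrane_depth_profile(s, (-15.0, 15.0))
        assert df.depth.iloc[0] == pytest.approx(-15.0)
        assert df["class"].iloc[0] == "embedded"

    def test_above_upper_leaflet_is_solvent(self):
        s = pl.Structure([self._bead(17.0, 1)])
        df = pl.membrane_depth_profile(s, (-15.0, 15.0))
        assert df.depth.iloc[0] == pytest.approx(2.0)
        assert df["class"].iloc[0] == "solvent"

    def test_belt_ring_at_leaflet_is_interfacial(self):
        ring = pl.Structure([self._bead(15.0, i + 1) for i in range(7)])
        df = pl.membrane_depth_profile(ring, (-15.0, 15.0))
        assert np.allclose(df.depth, 0.0)
        assert set(df["class"]) == {"interfacial"}

    def test_empty_selection_rejected(self):
        s = pl.Structure([self._bead(0.0, 1)])
        with pytest.raises(ValueError):
            pl.membrane_depth_profile(s, (-15.0, 15.0), residues={999})


class TestSuperposition:
    def test_self_rmsd_zero(self, plain_cylinder):
        res = pl.superpose_rmsd(plain_cylinder, plain_cylinder)
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)
        assert res.n_atoms == len(plain_cylinder)

    def test_rigid_transform_recovered(self, plain_cylinder):
        R, t = _rotation(3), np.array([1.0, -2.0, 3.0])
        moved = plain_cylinder.transformed(R, t)
        res = pl.superpose_rmsd(plain_cylinder, moved)
        assert res.rmsd < 1e-6
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3),
                           atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_symmetry(self, plain_cylinder):
        moved = plain_cylinder.transformed(_rotation(4), np.zeros(3))
        noisy = pl.Structure([
            replace(a, xyz=a.xyz + 0.1 * np.sin(a.serial + np.arange(3)))
            for a in moved.atoms])
        ab = pl.superpose_rmsd(plain_cylinder, noisy).rmsd
        ba = pl.superpose_rmsd(noisy, plain_cylinder).rmsd
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_matches_independent_kabsch(self, plain_cylinder):
        rng = np.random.default_rng(5)
        noisy = pl.Structure([
            replace(a, xyz=a.xyz + rng.normal(0, 0.3, 3))
            for a in plain_cylinder.atoms]).transformed(
                _rotation(6), np.array([2.0, 0.0, -1.0]))
        res = pl.superpose_rmsd(plain_cylinder, noisy)
        xa, xb = (np.array([a.xyz for a in s.atoms])
                  for s in (plain_cylinder, noisy))
        assert res.rmsd == pytest.approx(_kabsch_oracle(xa, xb), abs=1e-9)

    def test_gaussian_noise_rmsd_expectation(self):
        """sigma = 0.5 A per coordinate -> RMSD ~ 0.5*sqrt(3) A."""
        rng = np.random.default_rng(7)
        base = pl.make_barrel(pl.BarrelSpec(length=54.0, bead_spacing=1.5))
        atoms = base.atoms[:500]
        A = pl.Structure(atoms)
        vals = []
        for _ in range(20):
            B = pl.Structure([replace(a, xyz=a.xyz + rng.normal(0, 0.5, 3))
                              for a in atoms])
            vals.append(pl.superpose_rmsd(A, B).rmsd)
        expected = 0.5 * math.sqrt(3.0)
        assert abs(np.mean(vals) - expected) / expected < 0.05

    def test_unmatched_selection_reported(self, plain_cylinder):
        other = pl.Structure(plain_cylinder.atoms[:-1])
        with pytest.raises(ValueError, match="mismatch"):
            pl.superpose_rmsd(plain_cylinder, other)
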