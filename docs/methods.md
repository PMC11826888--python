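# Methods

## Units and conventions

All lengths are in Å, times in ps, charges in elementary charges (e),
temperatures in K.  Electrical quantities are converted only at reporting
boundaries: 1 e/ps = 1.602176634 × 10⁵ pA, and 1 e/(V·Å·ps) =
1.602176634 × 10⁴ mS/cm.  k_B is carried in eV/K so that q·E·D/(k_B·T) with
q in e and E in V/Å is a velocity in Å/ps.  Boxes are orthorhombic only;
triclinic input is rejected.  Frame coordinates are wrapped into [0, L) per
axis; trajectories require a strictly uniform frame spacing dt.

The pore-axis convention places z increasing from the extracellular cap end
toward the cytoplasmic (rivet) end; `principal_pore_axis` orients the
detected axis with a non-negative z component and both the axis and the
sign are caller-overridable.

## Structure input

PDB parsing is delegated to gemmi; on top of it the package applies its own
policies: alternate locations reduce to the highest-occupancy conformer
(ties broken by altloc letter), insertion codes remain part of residue
identity, and residue numbering follows the file verbatim.  Van der Waals
radii are resolved per element from a Bondi-style table (C 1.70, N 1.55,
O 1.52, S 1.80, H 1.20, P 1.80, fallback 1.80 Å), overridable per call; the
element falls back to the atom name's first alphabetic character when the
element column is blank.  The radius set behind published HOLE traces of
this pore family is not documented anywhere we could rely on, so the table
is a declared package choice, not an inference.

## Synthetic generators

The generators are pure functions of (spec, seed); no hidden RNG state.

**Bead barrels.**  `make_barrel` places beads along vertical strand lines at
radial distance r(z) + r_bead, where the designed lumen profile r(z) is the
pointwise minimum of Gaussian wells (σ = axial_width/2) dug into the base
radius, reaching each constriction's target radius exactly at its center.
Strands are replicated by n-fold rotation; both strands of a protomer share
residue numbering so a ring's lining deduplicates to one residue per
protomer.  The wild-type-emulating default is a 120 Å barrel, 7 protomers ×
2 strands, base radius 8.5 Å, with four 5 Å rings at z = 12, 26, 94 and
108 Å — two near each end, mirroring the layout of the R282/R220
(extracellular) and K238, K242/K244 (cytoplasmic) rings with the measured
~5 Å ring vs ~8–9 Å cavity contrast.  The K238A-emulating variant widens
only the third ring (z = 94 Å) to 7 Å.  Bead spacing is 1.5 Å with 1.7 Å
bead vdW radius; the axial bead discretization bounds profile errors by
about √(r² + (s/2)²) − r ≲ 0.03 Å at r ≈ 10 Å, and a 0.3 Å tolerance is
used throughout.

**Drift-diffusion electrolytes.**  Each ion steps independently with
per-axis Gaussian variance 2·D·dt plus an axial drift
μ = q·E_z·D/(k_B·T)·dt (Einstein relation).  The analytic mean current
I = Σᵢ qᵢμᵢ/(L_z·dt) is attached to the trajectory as ground truth.
Defaults: D = 0.2 Å²/ps (potassium-like), T = 298 K, dt = 10 ps, a
40 × 40 × 80 Å box.  Specs whose drift per step exceeds L_z/4 are rejected
because minimum-image unwrapping would be ambiguous.  These walkers carry
the statistical structure of an electrolyte under weak uniform field — not
ion–ion or ion–water interactions — so they validate estimators, not
force fields.

**Confined water.**  Water points are resampled i.i.d. each frame uniformly
inside the tube r < R(z) (no dynamics — sufficient for density-based
recovery and deliberately non-physical), bounded by a static bead wall at
R(z) + 0.3 Å with ~1 Å bead spacing.  Waters are named `OW`, wall beads
`WAL`, so the standard selections pick them apart.

## Radius profile and rings

At each grid z (default dz = 0.5 Å) the clearance of a sphere center c in
the slice plane is minᵢ(|c − xᵢ| − r_vdW,i) over all atoms within
r_max + max vdW of the plane.  `axial` mode evaluates the axis point only;
`optimized` mode maximizes clearance over in-plane centers with a 1 Å
coarse grid followed by Nelder–Mead refinement (xatol 10⁻⁴), seeded
additionally from the previous slice's optimum.  Two numerical guards
matter: the center is confined to a disk of radius `center_bound`
(default 5 Å) — without it the maximal sphere escapes the lumen sideways
wherever the wall exterior offers more clearance than a constriction — and
a capped slice resets the seeding so an open-end escape cannot poison
subsequent slices.  Clearances ≥ r_max (default 15 Å) are flagged `capped`;
negative best clearances are flagged `blocked` and the negative value is
recorded, so cap-region occlusion stays distinguishable from a 0 Å waist.
The deterministic search agrees with an exhaustive 0.05 Å in-plane grid to
better than 0.05 Å (tested), which is the accuracy claim we make in place
of Monte-Carlo equivalence.

Constriction rings are prominence-filtered local minima (find_peaks on the
negated radius) over contiguous open runs, kept when the minimum radius is
at or below `radius_ceiling` (7 Å) with topographic prominence ≥ 0.5 Å;
minima closer than `merge_window` (4 Å) merge keeping the deeper.  The
defaults were chosen so a four-ring geometry of ≈5 Å rings in an ≈8–9 Å
cavity is resolved; none of them is dictated by the underlying data.
Lining residues are the owners of the `n_nearest` (14, i.e. one per strand)
atoms by clearance within a ±3 Å slab of the ring.

## Water-accessibility radius

Density maps average per-frame voxel counts (default 1 Å spacing; voxel
edges are L/n so the grid tiles the box exactly) normalized by voxel
volume, so the integral equals the mean selected-atom count per frame.
Ring averaging takes voxel centers within [z − dz/2, z + dz/2) (dz = 1 Å)
binned into annuli of width dr = 0.5 Å.  The scan runs r outward from the
axis; while water/max(pore, ε) ≥ threshold it continues, and at the first
annulus below threshold the previous annulus' outer edge (k·dr) is
returned.  Threshold 1.0 (equal water and pore density defines the
boundary) and ε = 10⁻⁶ Å⁻³ are declared defaults; the recovered radius is
monotone non-increasing in the threshold by construction.  Annuli that
contain no voxel center — which happens near the axis whenever the box
tiles into an even number of voxels — carry no evidence and are skipped
rather than read as zero water; the no-water (`undefined`) decision uses
the innermost annulus that has data.  If the ratio never crosses, the
radius caps at r_max.  On the synthetic tubes the recovered radius is
accurate to one radial bin (the wall sits 0.3 Å outside the water, so the
crossing lands in the bin containing the true radius, smeared by ~1 voxel).

For molecular systems the intended selections are water oxygens (one point
per molecule) versus all non-water, non-ion heavy atoms; the selection
layer is name-based and caller-controlled.

## Currents and conductivity

Per-transition currents use I = Σᵢ qᵢΔzᵢ/(L_z·dt) with Δzᵢ mapped into
(−L_z/2, +L_z/2] (half-open, so an exact half-box displacement is positive).
By construction Σ_t I(t)·dt·L_z equals the total unwrapped charge
displacement exactly, and the estimator is linear in charges and additive
over disjoint ion sets — both are tested as invariants.  Means carry SEMs
from 5 contiguous block means (std/√n_blocks); no autocorrelation
correction beyond blocking is applied, and no empirical scaling factor is
ever applied to currents.  I–V curves are per-voltage means with
rectification ratios |I(+V)|/|I(−V)| for matched pairs.  Bulk conductivity
assumes a uniform axial field E_z = V/L_z (the voltage-imposition
convention is stated, since alternatives such as charge-imbalance setups
exist) and reports σ = ⟨I⟩/(E_z·Lx·Ly) in mS/cm.  On the synthetic
electrolytes σ must match Nernst–Einstein σ = Σ nᵢqᵢ²Dᵢ/(k_BT) within
3 SEM, and σ is linear in ion count.

A note on magnitudes: the 12.0 mS/cm (simulated) and 11.3 mS/cm
(experimental) figures used in the deviation arithmetic are roughly an
order of magnitude below commonly tabulated conductivities of 1 M KCl
(~110 mS/cm).  The package reproduces the printed arithmetic
(100·|12.0 − 11.3|/11.3 = 6.2%) as given and takes no position on the unit
question; the synthetic-electrolyte recovery checks are scale-free.

## Superposition and contacts

RMSD uses the Kabsch least-squares rotation (via
scipy's `Rotation.align_vectors`, proper rotation enforced) over atoms
matched 1:1 by (chain, resseq, icode, name); unmatched selections raise
with the first offending key.  Tests cross-check against an independent
SVD implementation and against the closed-form noise expectation
E[RMSD] ≈ σ√3 for i.i.d. Gaussian coordinate noise.

Polar contacts are distance-only: N/O pairs from different residues within
3.5 Å are H-bonds; basic side-chain N (Lys NZ, Arg NE/NH1/NH2, His
ND1/NE2 — histidine is included because it can carry a positive charge) to
acidic side-chain O (Asp OD1/OD2, Glu OE1/OE2) within 4.0 Å are salt
bridges, which take precedence when both criteria hold.  No angular term is
used because deposited models commonly lack hydrogens; both cutoffs are
configurable.  Interface summaries group inter-protomer contacts by chain
pair and report per-subunit means.

## Membrane depth

Given caller-supplied leaflet planes (the module never infers leaflets),
each residue's depth is the mean axial coordinate of its side-chain
terminal atoms (a per-residue-type table; single-bead residues use the
bead) minus the nearest leaflet plane, signed negative toward the bilayer
midplane.  Classification: |depth| < 2 Å interfacial, deeper negative
embedded, positive solvent — so a belt residue exactly at a leaflet plane
is interfacial while one 2 Å outside is solvent.

## Problem sizes and what passing shows

The test suite and the acceptance script run at desk scale chosen as
adequate for their statistical claims: barrels of ~1100 beads, water
systems of 1500 waters × 80 frames on 1 Å grids, electrolytes of 20–120
ions × 3000–5000 frames.  Stochastic acceptance uses 3-SEM bands
throughout.  Passing demonstrates correctness of the estimators against
analytic ground truth and internal invariants; it does not validate
force-field physics, water structure, or any property of real membranes,
because the generators supply statistical structure only.

## Known limitations

- The optimized radius profile assumes a lumen near the axis
  (`center_bound`); strongly kinked or laterally offset channels need a
  caller-supplied axis or a larger bound.
- The water-radius scan assumes an axial, water-filled lumen; non-axial
  pores and per-frame (time-resolved) radii are out of scope.
- Minimum-image current unwrapping requires per-frame displacements well
  below L_z/2; sparsely sampled trajectories violating this are not
  detected beyond the generator-side guard.
- Contact detection is purely geometric; no protonation-state inference or
  energetic scoring.
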