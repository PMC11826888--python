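# porelumen

Quantitative lumen analysis for β-barrel nanopores: maximal-sphere pore-radius
profiles with constriction-ring detection, water-accessibility radii from MD
density maps, ionic currents and I–V curves from ion displacements, rigid
Cα-RMSD superposition, and inter-protomer polar-contact networks — together
with synthetic generators (Cₙ-symmetric bead barrels, drift-diffusion
electrolytes, confined water) whose analytic ground truth makes every stage
testable without any structure downloads or MD engine.

It is written for structural biologists and nanopore engineers who work with
pore-forming toxins such as aerolysin — a heptameric toxin whose 120 Å,
14-stranded transmembrane β-barrel (two antiparallel strands per protomer)
is a workhorse single-molecule sensor.  The lumen of such a pore carries
constriction rings — symmetric rings of side chains (R282, R220, K238,
K242/K244 in aerolysin) forming local radius minima that act as the sensing
zones — and the quantities this package computes (ring radii and positions,
water-accessible radii, current–voltage response) are exactly the ones used
to rationalize and engineer their sensitivity.

## Core quantities

**Pore radius profile.** At each position *z* along the pore axis the radius
is the largest sphere centered in the plane through *z* touching no atom,

&nbsp;&nbsp;&nbsp;&nbsp;R(z) = max_c min_i ( |c − x_i| − r_vdW,i ),

the construction popularized by HOLE.  The in-plane center search is a
deterministic coarse grid plus Nelder–Mead refinement rather than the
original Monte-Carlo walk, so profiles are exactly reproducible.
Constriction rings are prominence-filtered local minima of R(z).

**Water-accessibility radius.** From a trajectory, 3D density maps of water
and pore atoms are averaged over frames; at each *z* both are ring-averaged
in annuli [r, r + dr) about the axis, and r is scanned outward until the
water/pore density ratio drops below a threshold — the previous annulus'
outer edge is the water-accessibility radius at that *z*.

**Ionic current.** Between consecutive frames,

&nbsp;&nbsp;&nbsp;&nbsp;I(t) = 1/(L_z·Δt) · Σ_i q_i·Δz_i,

with Δz_i minimum-image unwrapped; trajectory means carry block-averaged
SEMs, I–V curves report rectification ratios, and homogeneous-electrolyte
runs yield the bulk conductivity σ = ⟨I⟩/(E_z·A), which for the synthetic
drift-diffusion walkers must agree with the Nernst–Einstein closed form
σ = Σ n_i q_i² D_i /(k_B T).

**Superposition RMSD** uses the Kabsch least-squares rotation over atoms
matched by (chain, residue, insertion code, atom name); **polar contacts**
are distance-only N/O pairs (H-bonds ≤ 3.5 Å) and basic-N/acidic-O pairs
(salt bridges ≤ 4.0 Å), summarized per protomer interface.

## Worked example

```python
import porelumen as pl
from porelumen.constants import E_PER_PS_TO_PA

# a wild-type-emulating barrel: four 5 A rings in an 8.5 A cavity
barrel = pl.make_barrel(pl.wt_barrel_spec())
axis = pl.principal_pore_axis(barrel)
profile = pl.radius_profile(barrel, axis, dz=0.5)
for ring in pl.detect_constrictions(profile):
    lining = pl.lining_residues(barrel, axis, ring)
    print(f"ring at z = {ring.z_min:+6.1f} A   radius = {ring.radius_min:.2f} A   "
          f"lined by {len(lining)} residues")

# a drift-diffusion electrolyte with a closed-form expected current
spec = pl.IonWalkSpec(n_cation=10, n_anion=10, D=0.2, E_z=1e-4,
                      dt=10.0, n_frames=5000, seed=1)
traj = pl.make_ion_trajectory(spec)
mean, sem = pl.mean_current(traj)
print(f"mean current {mean:.1f} +/- {sem:.1f} pA "
      f"(analytic {spec.expected_current * E_PER_PS_TO_PA:.1f} pA)")
print(f"deviation vs experiment: {pl.relative_deviation(12.0, 11.3)}%")
```

prints

```
ring at z =  -48.0 A   radius = 5.00 A   lined by 7 residues
ring at z =  -34.5 A   radius = 5.03 A   lined by 7 residues
ring at z =  +34.5 A   radius = 5.03 A   lined by 7 residues
ring at z =  +48.0 A   radius = 5.00 A   lined by 7 residues
mean current 48.7 +/- 40.2 pA (analytic 31.2 pA)
deviation vs experiment: 6.2%
```

Four rings, two near each end of the barrel, are recovered at their designed
positions (the grid step is 0.5 Å) with radii at the designed 5 Å; each ring
is lined by one residue from each of the seven protomers.  The electrolyte
mean current agrees with the Einstein-relation drift prediction within its
statistical error, and the final line is the relative deviation between a
simulated bulk conductivity of 12.0 mS/cm and the experimental 11.3 mS/cm
reference for the same electrolyte.

The same analyses are available from the shell via the `porelumen` console
script (`synth`, `profile`, `water-radius`, `current`, `iv`, `rmsd`,
`contacts`); every run writes a `.config.json` echo of its parameters next
to its outputs.

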