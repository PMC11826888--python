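import numpy as np
import pytest
from hypothesis import settings

import porelumen as pl

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def wt_barrel():
    """Wild-type-emulating barrel: four 5 A rings in an 8.5 A cavity."""
    return pl.make_barrel(pl.wt_barrel_spec())


@pytest.fixture(scope="session")
def wt_axis(wt_barrel):
    return pl.principal_pore_axis(wt_barrel)


@pytest.fixture(scope="session")
def wt_profile(wt_barrel, wt_axis):
    return pl.radius_profile(wt_barrel, wt_axis, dz=0.5)


@pytest.fixture(scope="session")
def plain_cylinder():
    """Constriction-free barrel: analytic cylinder limit, radius 10 A."""
    return pl.make_barrel(pl.BarrelSpec(base_radius=10.0, length=40.0))


def make_pdb(atoms):
    """Build PDB text from (serial, name, altloc, resname, chain, resseq,
    x, y, z, occ, element) tuples."""
    lines = []
    for (serial, name, alt, resname, chain, resseq, x, y, z, occ, el) in atoms:
        nm = name if len(name) >= 4 else f" {name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {nm:<4s}{alt or ' ':1s}{resname:>3s} "
            f"{chain:1s}{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {el:>2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"
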