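"""Polar-contact and salt-bridge networks within and between protomers.

Criteria are geometric and distance-only (deposited models usually lack
hydrogens, so no donor-H-acceptor angle is evaluated): an H-bond is any
N/O--N/O heavy-atom pair from different residues within ``hbond_cutoff``;
a salt bridge is a basic side-chain nitrogen (Lys NZ, Arg NE/NH1/NH2,
His ND1/NE2 — histidine is treated as a potential donor since it can be
charged) within ``salt_cutoff`` of an acidic side-chain oxygen (Asp
OD1/OD2, Glu OE1/OE2).  A pair meeting both criteria is classified once,
as a salt bridge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io import AtomRecord, Structure

__all__ = ["Contact", "InterfaceSummary", "polar_contacts",
           "interface_network"]

_BASIC_SIDECHAIN_N = {
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}
_ACIDIC_SIDECHAIN_O = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
}


@dataclass(frozen=True)
class Contact:
    atom_a: tuple               # (chain, resseq, icode, name)
    atom_b: tuple
    res_a: tuple                # (chain, resname, resseq, icode)
    res_b: tuple
    distance: float             # A
    kind: str                   # "hbond" | "salt_bridge"
    interface: str              # "intra" | "inter"


def _is_salt_pair(a: AtomRecord, b: AtomRecord) -> bool:
    ka, kb = (a.resname, a.name), (b.resname, b.name)
    return ((ka in _BASIC_SIDECHAIN_N and kb in _ACIDIC_SIDECHAIN_O)
            or (kb in _BASIC_SIDECHAIN_N and ka in _ACIDIC_SIDECHAIN_O))


def polar_contacts(struct: Structure, hbond_cutoff: float = 3.5,
                   salt_cutoff: float = 4.0) -> list[Contact]:
    """All polar contacts in a structure, canonically ordered.

    Atoms must carry element types; each unordered pair appears once,
    oriented by (chain, resseq, icode, name) order, and the output is
    sorted by (interface chains, residue numbers, distance).
    """
    polar = [a for a in struct.atoms if a.element.strip().upper() in ("N", "O")]
    for a in struct.atoms:
        if not a.element.strip():
            raise ValueError(
                f"atom {a.name} in {a.residue_id} has no element type")
    if not polar:
        return []
    xyz = np.array([a.xyz for a in polar])
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=max(hbond_cutoff, salt_cutoff))
    out: list[Contact] = []
    for i, j in pairs:
        a, b = polar[i], polar[j]
        if a.residue_id == b.residue_id:
            continue
        d = float(np.linalg.norm(a.xyz - b.xyz))
        if _is_salt_pair(a, b) and d <= salt_cutoff:
            kind = "salt_bridge"
        elif d <= hbond_cutoff:
            kind = "hbond"
        else:
            continue
        if (b.chain_id, b.resseq, b.icode, b.name) < \
           (a.chain_id, a.resseq, a.icode, a.name):
            a, b = b, a
        out.append(Contact(
            atom_a=(a.chain_id, a.resseq, a.icode, a.name),
            atom_b=(b.chain_id, b.resseq, b.icode, b.name),
            res_a=a.residue_id, res_b=b.residue_id, distance=d, kind=kind,
            interface="intra" if a.chain_id == b.chain_id else "inter"))
    out.sort(key=lambda c: (c.atom_a[0], c.atom_b[0], c.atom_a[1],
                            c.atom_b[1], c.distance))
    return out


@dataclass
class InterfaceSummary:
    """Contacts grouped per protomer pair, with per-subunit means."""

    pairs: dict                 # (chain_a, chain_b) -> {"hbond": n, "salt_bridge": n}
    residue_pairs: dict         # (chain_a, chain_b) -> list[(res_a, res_b, kind)]
    n_protomers: int
    per_subunit: dict           # kind -> mean inter-protomer count per subunit

    def total(self, kind: str | None = None) -> int:
        if kind is None:
            return sum(sum(v.values()) for v in self.pairs.values())
        return sum(v.get(kind, 0) for v in self.pairs.values())


def interface_network(contacts: Sequence[Contact],
                      n_protomers: int | None = None) -> InterfaceSummary:
    """Summarize inter-protomer contacts per adjacent chain pair.

    ``n_protomers`` defaults to the number of distinct chains seen; the
    per-subunit figures are total inter-protomer counts divided by it.
    """
    pairs: dict = {}
    residue_pairs: dict = {}
    chains: set[str] = set()
    for c in contacts:
        chains.update((c.res_a[0], c.res_b[0]))
        if c.interface != "inter":
            continue
        key = tuple(sorted((c.res_a[0], c.res_b[0])))
        pairs.setdefault(key, {"hbond": 0, "salt_bridge": 0})
        pairs[key][c.kind] += 1
        residue_pairs.setdefault(key, []).append((c.res_a, c.res_b, c.kind))
    n = n_protomers if n_protomers is not None else max(len(chains), 1)
    per_subunit = {
        kind: sum(v.get(kind, 0) for v in pairs.values()) / n
        for kind in ("hbond", "salt_bridge")}
    return InterfaceSummary(pairs=pairs, residue_pairs=residue_pairs,
                            n_protomers=n, per_subunit=per_subunit)
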