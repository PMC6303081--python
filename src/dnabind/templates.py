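"""Residue templates: ideal geometry, connectivity and hydrogen placement.

Templates for the 20 standard amino acids and the 4 deoxyribonucleotides are
derived from the Chemical Component Dictionary bundled with biotite.  Free
monomers carry leaving atoms (C-terminal OXT/HXT, the second amide proton,
acid protons, the 5'-OP3 phosphate oxygen and the 3'-OH proton); those are
stripped so that templates describe in-chain residues in their default
charge states at neutral pH: Arg/Lys +1, Asp/Glu -1, His neutral (Nd1-H
tautomer), one phosphate (-1) per nucleotide.

Hydrogens are rebuilt geometrically: every template hydrogen stores internal
coordinates (bond length, angle, dihedral) relative to three reference atoms,
and :func:`add_hydrogens` replays them onto actual coordinates with NeRF.
The backbone amide H is special-cased to lie trans to the preceding carbonyl.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import biotite.structure.info as struc_info

from .geometry import angle, dihedral, place_atom

AMINO_ACIDS = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in AMINO_ACIDS.items()}
NUCLEOTIDES = {"DA", "DC", "DG", "DT"}
DNA_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PROTEIN_BACKBONE = ("N", "CA", "C", "O")
# Sugar-phosphate backbone of DNA (restrained set during minimization).
DNA_BACKBONE = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'", "O4'", "C1'", "C2'")

# Atoms of the free CCD monomer that do not exist in a chain at neutral pH.
_LEAVING = {
    "common_aa": {"OXT", "HXT", "H2"},
    "ASP": {"HD2"},
    "GLU": {"HE2"},
    "HIS": {"HE2"},   # neutral tautomer, proton on ND1
    "PRO": {"H"},     # backbone N is tertiary inside a chain
    "common_nt": {"OP3", "HOP3", "HOP2", "HO3'", "HO5'"},
}

# Side-chain dihedral (chi) definitions, standard atom quadruplets.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [],
    "GLY": [],
    "PRO": [],  # ring: not rotamer-sampled
}


@dataclass(frozen=True)
class HydrogenRule:
    """Internal-coordinate recipe for one template hydrogen."""
    name: str
    parent: str        # bonded heavy atom
    ref2: str          # neighbour of parent
    ref3: str          # neighbour of ref2 (dihedral reference)
    bond: float        # Angstrom
    theta: float       # radians, ref2-parent-H
    phi: float         # radians, ref3-ref2-parent-H


@dataclass(frozen=True)
class ResidueTemplate:
    name: str
    atom_names: tuple[str, ...]           # heavy atoms, template order
    elements: tuple[str, ...]
    coords: np.ndarray                    # (n_heavy, 3) ideal geometry
    bonds: tuple[tuple[str, str], ...]    # heavy-heavy bonds
    hydrogen_rules: tuple[HydrogenRule, ...]
    h_parent: dict = field(default_factory=dict)  # H name -> parent heavy atom
    positions: dict = field(default_factory=dict)  # every atom (incl. H) -> ideal xyz

    @property
    def n_hydrogens(self) -> int:
        return len(self.hydrogen_rules)

    def heavy_index(self, name: str) -> int:
        return self.atom_names.index(name)


def _leaving_atoms(res_name: str) -> set[str]:
    if res_name in AMINO_ACIDS:
        extra = _LEAVING.get(res_name, set())
        return _LEAVING["common_aa"] | extra
    if res_name in NUCLEOTIDES:
        return _LEAVING["common_nt"]
    raise KeyError(res_name)


@lru_cache(maxsize=None)
def get_template(res_name: str) -> ResidueTemplate:
    """Template for one standard residue; raises KeyError for anything else."""
    if res_name not in AMINO_ACIDS and res_name not in NUCLEOTIDES:
        raise KeyError(f"no template for residue kind {res_name!r}")
    ccd = struc_info.residue(res_name)
    drop = _leaving_atoms(res_name)
    keep = np.array([n not in drop for n in ccd.atom_name])
    ccd = ccd[keep]
    names = [str(n) for n in ccd.atom_name]
    elements = [str(e).capitalize() for e in ccd.element]
    coords = np.asarray(ccd.coord, dtype=float)

    raw_bonds = struc_info.bonds_in_residue(res_name)
    bonded: dict[str, list[str]] = {n: [] for n in names}
    for (a, b) in raw_bonds:
        if a in bonded and b in bonded:
            bonded[a].append(b)
            bonded[b].append(a)

    pos = {n: coords[i] for i, n in enumerate(names)}
    is_h = [e == "H" for e in elements]
    heavy = [n for n, h in zip(names, is_h) if not h]
    heavy_set = set(heavy)

    heavy_bonds = tuple(
        (a, b) for (a, b) in raw_bonds
        if a in heavy_set and b in heavy_set
    )

    rules = []
    h_parent = {}
    for n, h in zip(names, is_h):
        if not h:
            continue
        parents = [x for x in bonded[n] if x in heavy_set]
        if len(parents) != 1:
            raise ValueError(f"hydrogen {n} in {res_name} has no unique parent")
        p = parents[0]
        h_parent[n] = p
        # deterministic reference choice: heavy neighbours first, template order
        cands2 = sorted(
            (x for x in bonded[p] if x != n and x in heavy_set),
            key=names.index,
        )
        if not cands2:  # parent bonded only to hydrogens (does not occur here)
            raise ValueError(f"no heavy reference for {n} in {res_name}")
        r2 = cands2[0]
        # dihedral reference: prefer an atom rigidly attached to the parent
        # (its other heavy neighbour) so hydrogens ride with the local group;
        # only fall back to ref2's neighbours for terminal rotatable groups.
        if len(cands2) > 1:
            r3 = cands2[1]
        else:
            cands3 = sorted(
                (x for x in bonded[r2] if x != p and x in heavy_set),
                key=names.index,
            )
            if not cands3:
                raise ValueError(f"cannot frame hydrogen {n} in {res_name}")
            r3 = cands3[0]
        rules.append(HydrogenRule(
            name=n, parent=p, ref2=r2, ref3=r3,
            bond=float(np.linalg.norm(pos[n] - pos[p])),
            theta=angle(pos[r2], pos[p], pos[n]),
            phi=dihedral(pos[r3], pos[r2], pos[p], pos[n]),
        ))

    heavy_idx = [names.index(n) for n in heavy]
    return ResidueTemplate(
        name=res_name,
        atom_names=tuple(heavy),
        elements=tuple(elements[names.index(n)] for n in heavy),
        coords=coords[heavy_idx],
        bonds=heavy_bonds,
        hydrogen_rules=tuple(rules),
        h_parent=h_parent,
        positions={n: coords[i].copy() for i, n in enumerate(names)},
    )


def residue_kind(res_name: str) -> str:
    """'protein', 'dna' or 'other'."""
    if res_name in AMINO_ACIDS:
        return "protein"
    if res_name in NUCLEOTIDES:
        return "dna"
    return "other"


def template_hydrogen_positions(
    res_name: str,
    heavy_pos: dict[str, np.ndarray],
    prev_c: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Ideal hydrogen positions for a residue given its heavy-atom coordinates.

    ``prev_c`` is the carbonyl C (protein) of the preceding residue; when
    given, the backbone amide H is placed trans to it in the peptide plane,
    which the free-monomer template cannot encode.
    """
    tpl = get_template(res_name)
    out: dict[str, np.ndarray] = {}
    for rule in tpl.hydrogen_rules:
        if rule.parent not in heavy_pos or rule.ref2 not in heavy_pos \
                or rule.ref3 not in heavy_pos:
            continue
        if rule.name == "H" and rule.parent == "N" and prev_c is not None:
            # amide H: in the C(prev)-N-CA plane, opposite the bisector
            n, ca = heavy_pos["N"], heavy_pos["CA"]
            u = (ca - n) / np.linalg.norm(ca - n)
            v = (prev_c - n) / np.linalg.norm(prev_c - n)
            d = -(u + v)
            d /= np.linalg.norm(d)
            out["H"] = n + rule.bond * d
            continue
        out[rule.name] = place_atom(
            heavy_pos[rule.ref3], heavy_pos[rule.ref2], heavy_pos[rule.parent],
            rule.bond, rule.theta, rule.phi,
        )
    return out
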