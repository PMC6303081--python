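"""Typed protein-DNA complex model and PDB-format I/O.

The central container is :class:`ComplexStructure`: chains of residues of
atoms, plus an assignment of chains to two binding partners (partner 1 =
protein, partner 2 = DNA).  Parsing and writing go through biotite's PDB
reader/writer; on top of that this module enforces the input contract of the
prediction pipeline: at least two chains, one model (first NMR model by
default), highest-occupancy alternate conformers, standard residues only,
and an interface area above 100 A^2 between the assigned partners.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .templates import (
    AMINO_ACIDS, NUCLEOTIDES, ONE_TO_THREE,
    PROTEIN_BACKBONE, DNA_BACKBONE, residue_kind, get_template,
    template_hydrogen_positions,
)

logger = logging.getLogger(__name__)

INTERFACE_AREA_GATE = 100.0  # A^2, minimum buried area for "interacting"


class StructureError(ValueError):
    """Raised when an input structure violates the pipeline's contract."""


@dataclass
class AtomRecord:
    """One atom with the per-atom quantities entering the energy terms."""
    name: str
    element: str
    position: np.ndarray                 # (3,), Angstrom
    partial_charge: float = 0.0          # e
    lj_rmin_half: float = 0.0            # Angstrom
    lj_epsilon: float = 0.0              # kcal/mol
    pb_radius: float = 0.0               # Angstrom
    is_backbone: bool = False
    is_hydrogen: bool = False

    def copy(self) -> "AtomRecord":
        return AtomRecord(
            self.name, self.element, self.position.copy(),
            self.partial_charge, self.lj_rmin_half, self.lj_epsilon,
            self.pb_radius, self.is_backbone, self.is_hydrogen,
        )


@dataclass
class ResidueRecord:
    chain_id: str
    number: int                          # author numbering
    icode: str                           # insertion code, "" if none
    name: str                            # 3-letter PDB name (ALA, DA, ...)
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def kind(self) -> str:
        return residue_kind(self.name)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.name}{self.number}{self.icode}"

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not in residue {self.label}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def copy(self) -> "ResidueRecord":
        return ResidueRecord(
            self.chain_id, self.number, self.icode, self.name,
            [a.copy() for a in self.atoms],
        )


@dataclass(frozen=True)
class Mutation:
    """A single missense substitution in the protein partner."""
    chain_id: str
    residue_number: int
    wt_aa: str                           # one-letter
    mut_aa: str                          # one-letter
    icode: str = ""

    def __post_init__(self):
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in ONE_TO_THREE:
                raise ValueError(f"unknown amino acid {aa!r}")

    def __str__(self) -> str:
        return f"{self.chain_id} {self.wt_aa}{self.residue_number}{self.icode}{self.mut_aa}"

    @classmethod
    def parse(cls, text: str) -> "Mutation":
        """Parse 'CHAIN WT POS MUT' (e.g. 'A R 124 A') or compact 'A:R124A'."""
        text = text.strip()
        if ":" in text:
            chain, rest = text.split(":", 1)
            wt, core, mut = rest[0], rest[1:-1], rest[-1]
        else:
            parts = text.split()
            if len(parts) != 4:
                raise ValueError(f"cannot parse mutation {text!r}")
            chain, wt, core, mut = parts
        icode = ""
        if core and core[-1].isalpha():
            core, icode = core[:-1], core[-1]
        return cls(chain, int(core), wt.upper(), mut.upper(), icode)


@dataclass
class ComplexStructure:
    """A protein-DNA complex: chains of residues plus partner assignment."""
    chains: dict[str, list[ResidueRecord]]
    partner1: tuple[str, ...] = ()       # protein chain ids
    partner2: tuple[str, ...] = ()       # DNA chain ids
    provenance: str = ""

    # -- basic views -------------------------------------------------------
    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self, chain_ids=None):
        if chain_ids is None:
            chain_ids = self.chain_ids
        for cid in chain_ids:
            yield from self.chains[cid]

    def atoms(self, chain_ids=None):
        for res in self.residues(chain_ids):
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def coords(self, chain_ids=None) -> np.ndarray:
        return np.array([a.position for a in self.atoms(chain_ids)], dtype=float)

    def set_coords(self, coords: np.ndarray, chain_ids=None) -> None:
        for a, x in zip(self.atoms(chain_ids), coords, strict=True):
            a.position = np.asarray(x, dtype=float).copy()

    def find_residue(self, chain_id: str, number: int, icode: str = "") -> ResidueRecord:
        if chain_id not in self.chains:
            raise StructureError(f"chain {chain_id!r} not in structure")
        for res in self.chains[chain_id]:
            if res.number == number and res.icode == icode:
                return res
        raise StructureError(
            f"residue {number}{icode} not found in chain {chain_id}")

    def copy(self) -> "ComplexStructure":
        return ComplexStructure(
            {cid: [r.copy() for r in residues] for cid, residues in self.chains.items()},
            self.partner1, self.partner2, self.provenance,
        )

    def subset(self, chain_ids) -> "ComplexStructure":
        """New structure containing only the given chains (copied)."""
        chain_ids = tuple(chain_ids)
        return ComplexStructure(
            {cid: [r.copy() for r in self.chains[cid]] for cid in chain_ids},
            tuple(c for c in self.partner1 if c in chain_ids),
            tuple(c for c in self.partner2 if c in chain_ids),
            self.provenance,
        )

    def transformed(self, r: np.ndarray, t: np.ndarray) -> "ComplexStructure":
        out = self.copy()
        for a in out.atoms():
            a.position = r @ a.position + t
        return out


# --------------------------------------------------------------------------
# parsing / writing
# --------------------------------------------------------------------------

def parse_structure(pdb_text: str, model_index: int = 1) -> ComplexStructure:
    """Read PDB-format text into a :class:`ComplexStructure`.

    ``model_index`` is 1-based; the default takes the first model (the
    convention for NMR ensembles).  Alternate locations are resolved to the
    highest-occupancy conformer (ties: first listed).  Non-standard residues
    (waters, ligands, modified residues) are dropped with a warning.
    """
    try:
        pdb = PDBFile.read(io.StringIO(pdb_text))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            arr = pdb.get_structure(model=model_index, altloc="occupancy",
                                    extra_fields=["b_factor"])
    except Exception as exc:
        raise StructureError(f"cannot parse PDB text: {exc}") from exc

    chains: dict[str, list[ResidueRecord]] = {}
    dropped: set[str] = set()
    for start, stop in zip(*_residue_bounds(arr)):
        res_name = str(arr.res_name[start])
        cid = str(arr.chain_id[start])
        if residue_kind(res_name) == "other":
            dropped.add(res_name)
            continue
        res = ResidueRecord(
            chain_id=cid,
            number=int(arr.res_id[start]),
            icode=str(arr.ins_code[start]).strip(),
            name=res_name,
        )
        for i in range(start, stop):
            name = str(arr.atom_name[i])
            element = str(arr.element[i]).capitalize()
            res.atoms.append(AtomRecord(
                name=name,
                element=element,
                position=np.asarray(arr.coord[i], dtype=float).copy(),
                is_hydrogen=(element == "H"),
                is_backbone=_is_backbone(res_name, name),
            ))
        chains.setdefault(cid, []).append(res)

    if dropped:
        logger.warning("dropped non-standard residues: %s", sorted(dropped))
    chains = {cid: residues for cid, residues in chains.items() if residues}
    if len(chains) < 2:
        raise StructureError(
            "the structure file should contain at least two chains "
            f"(found {len(chains)})")
    return ComplexStructure(chains, provenance=f"model {model_index}")


def _residue_bounds(arr) -> tuple[np.ndarray, np.ndarray]:
    starts = struc.get_residue_starts(arr)
    return starts, np.append(starts[1:], len(arr))


def _is_backbone(res_name: str, atom_name: str) -> bool:
    if res_name in AMINO_ACIDS:
        return atom_name in PROTEIN_BACKBONE
    if res_name in NUCLEOTIDES:
        return atom_name in DNA_BACKBONE
    return False


def write_structure(structure: ComplexStructure, destination=None) -> str:
    """Serialize to PDB text; optionally also write to a path/handle.

    Round-trips through :func:`parse_structure` with identical atom names,
    numbering and coordinates to 1e-3 A (the PDB fixed-point precision).
    """
    n = structure.n_atoms
    if n == 0:
        raise StructureError("cannot write an empty structure")
    arr = struc.AtomArray(n)
    i = 0
    for cid in structure.chain_ids:
        for res in structure.chains[cid]:
            for a in res.atoms:
                arr.chain_id[i] = cid
                arr.res_id[i] = res.number
                arr.ins_code[i] = res.icode
                arr.res_name[i] = res.name
                arr.atom_name[i] = a.name
                arr.element[i] = a.element.upper()
                arr.coord[i] = a.position
                arr.hetero[i] = False
                i += 1
    pdb = PDBFile()
    pdb.set_structure(arr)
    text = "\n".join(pdb.lines) + "\n"
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            with open(destination, "w") as fh:
                fh.write(text)
    return text


# --------------------------------------------------------------------------
# partner assignment and interface area
# --------------------------------------------------------------------------

def assign_partners(structure: ComplexStructure, p1, p2,
                    enforce_interface: bool = True) -> ComplexStructure:
    """Restrict to the selected chains and assign protein/DNA partners.

    Partner 1 must contain only amino-acid chains, partner 2 only
    deoxyribonucleotide chains, and the two must bury more than 100 A^2 of
    solvent-accessible surface between them to count as interacting.
    """
    p1, p2 = tuple(p1), tuple(p2)
    if not p1 or not p2:
        raise StructureError("both partners should include at least one chain")
    if set(p1) & set(p2):
        raise StructureError("partner chain sets must be disjoint")
    for cid in (*p1, *p2):
        if cid not in structure.chains:
            raise StructureError(f"chain {cid!r} not present in structure")
    for cid in p1:
        kinds = {r.kind for r in structure.chains[cid]}
        if kinds != {"protein"}:
            raise StructureError(f"partner-1 chain {cid!r} is not all protein")
    for cid in p2:
        kinds = {r.kind for r in structure.chains[cid]}
        if kinds != {"dna"}:
            raise StructureError(f"partner-2 chain {cid!r} is not all DNA")

    out = structure.subset(p1 + p2)
    out.partner1, out.partner2 = p1, p2
    if enforce_interface:
        area = compute_interface_area(out)
        if area <= INTERFACE_AREA_GATE:
            raise StructureError(
                f"partners bury only {area:.1f} A^2 "
                f"(<= {INTERFACE_AREA_GATE:.0f} A^2): not interacting")
    return out


def compute_interface_area(structure: ComplexStructure) -> float:
    """Buried solvent-accessible area between the two partners (A^2).

    SASA(p1) + SASA(p2) - SASA(complex), with the unbound partners taken
    rigidly from the complex coordinates.
    """
    from .sasa import total_sasa  # local import to avoid cycle
    if not structure.partner1 or not structure.partner2:
        raise StructureError("partners not assigned")
    a1 = total_sasa(structure, chain_ids=structure.partner1)
    a2 = total_sasa(structure, chain_ids=structure.partner2)
    a12 = total_sasa(structure)
    return a1 + a2 - a12


# --------------------------------------------------------------------------
# hydrogen / heavy-atom completion
# --------------------------------------------------------------------------

def complete_heavy_atoms(structure: ComplexStructure) -> ComplexStructure:
    """Rebuild missing heavy side-chain atoms from the residue templates.

    Backbone atoms must be present; each residue's template is superimposed
    on the shared atoms and missing heavy atoms are copied over.
    """
    from .geometry import kabsch, apply_rigid
    out = structure.copy()
    for res in out.residues():
        tpl = get_template(res.name)
        have = {a.name for a in res.atoms}
        missing = [n for n in tpl.atom_names if n not in have]
        if not missing:
            continue
        shared = [n for n in tpl.atom_names if n in have]
        if len(shared) < 3:
            raise StructureError(
                f"residue {res.label}: too few atoms to rebuild side chain")
        tpl_pos = np.array([tpl.coords[tpl.heavy_index(n)] for n in shared])
        act_pos = np.array([res.atom(n).position for n in shared])
        r, t = kabsch(tpl_pos, act_pos)
        for n in missing:
            p = apply_rigid(tpl.coords[tpl.heavy_index(n)], r, t)
            res.atoms.append(AtomRecord(
                name=n, element=tpl.elements[tpl.heavy_index(n)],
                position=np.asarray(p, dtype=float),
                is_backbone=_is_backbone(res.name, n),
            ))
        # keep template ordering for reproducible output
        order = {n: i for i, n in enumerate(tpl.atom_names)}
        res.atoms.sort(key=lambda a: order.get(a.name, len(order)))
    return out


def add_hydrogens(structure: ComplexStructure) -> ComplexStructure:
    """Add the template hydrogen set to every residue (idempotent).

    Hydrogens already present are kept in place; heavy atoms never move.
    Residues of unknown kind are rejected.
    """
    out = structure.copy()
    for cid in out.chain_ids:
        residues = out.chains[cid]
        for i, res in enumerate(residues):
            tpl = get_template(res.name)   # KeyError -> caller sees residue name
            have = {a.name for a in res.atoms}
            heavy_pos = {a.name: a.position for a in res.atoms if not a.is_hydrogen}
            prev_c = None
            if res.kind == "protein" and i > 0 and residues[i - 1].kind == "protein" \
                    and residues[i - 1].has_atom("C"):
                prev_c = residues[i - 1].atom("C").position
            hpos = template_hydrogen_positions(res.name, heavy_pos, prev_c=prev_c)
            order = {r.name: k for k, r in enumerate(tpl.hydrogen_rules)}
            for name in sorted(hpos, key=order.get):
                if name in have:
                    continue
                res.atoms.append(AtomRecord(
                    name=name, element="H",
                    position=np.asarray(hpos[name], dtype=float),
                    is_hydrogen=True,
                ))
    return out
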