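"""The nine structural features scored by the binding-affinity model.

For a single mutation the predictor consumes, in this order:

- ``sa_ratio_com_p2``     SASA(complex) / SASA(DNA partner), wild type
- ``ddg_solv``            change (mut - wt) in polar solvation binding energy
                          dG_solv = G_com - G_p1 - G_p2 (Poisson, eps 2/80)
- ``d_nhbond_p1p2``       change in protein-DNA hydrogen-bond count
- ``elec_mut_p1p2``       Coulomb energy between partners within 10 A (mutant)
- ``nhbond_wt_site_all``  H-bonds between the mutated site and everything else
                          in the wild type
- ``l_mut``               length of the mutated protein chain (residues)
- ``dd_evdw_site_all``    change in Lennard-Jones energy between the site and
                          all atoms within 10 A of it
- ``d_e_fold``            contact-potential change at the site (folding proxy)
- ``location_mut``        1 if the mutated residue sits at the interface

All energies are kcal/mol; counts are integers; the interface flag is 0/1.
Every term is computed on minimized structures with unbound partners
extracted rigidly from the complex.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from functools import lru_cache
from importlib.resources import files

import numpy as np
from scipy.spatial import cKDTree

from .params import COULOMB_CONSTANT, parameterize
from .pbsolver import PBSettings, pb_solvation_energy
from .sasa import total_sasa, residue_sasa
from .hbonds import (
    HBondCriteria, count_hbonds, chain_selector, residue_selector,
    complement_selector,
)
from .structure import ComplexStructure, Mutation, StructureError
from .templates import AMINO_ACIDS

SITE_CUTOFF = 10.0          # A, site-vs-all and partner-partner cutoffs
CONTACT_CUTOFF = 6.5        # A, Cbeta-Cbeta contact for the fold potential
INTERFACE_SASA_TOL = 1e-3   # A^2, strict-burial tolerance

FEATURE_NAMES = (
    "sa_ratio_com_p2", "ddg_solv", "d_nhbond_p1p2", "elec_mut_p1p2",
    "nhbond_wt_site_all", "l_mut", "dd_evdw_site_all", "d_e_fold",
    "location_mut",
)


@dataclass(frozen=True)
class FeatureVector:
    sa_ratio_com_p2: float
    ddg_solv: float
    d_nhbond_p1p2: float
    elec_mut_p1p2: float
    nhbond_wt_site_all: float
    l_mut: float
    dd_evdw_site_all: float
    d_e_fold: float
    location_mut: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


# --------------------------------------------------------------------------
# flat atom views
# --------------------------------------------------------------------------

def _atom_table(structure: ComplexStructure):
    parameterize(structure)
    pos, q, rmin, eps, resk = [], [], [], [], []
    for cid in structure.chain_ids:
        for ri, res in enumerate(structure.chains[cid]):
            for a in res.atoms:
                pos.append(a.position)
                q.append(a.partial_charge)
                rmin.append(a.lj_rmin_half)
                eps.append(a.lj_epsilon)
                resk.append((cid, ri))
    return (np.asarray(pos), np.asarray(q), np.asarray(rmin),
            np.asarray(eps), resk)


def _site_index(structure, mutation_or_site):
    """(chain_id, residue_index) of a site given a Mutation or address."""
    if isinstance(mutation_or_site, Mutation):
        cid = mutation_or_site.chain_id
        number = mutation_or_site.residue_number
        icode = mutation_or_site.icode
    else:
        cid, number, icode = mutation_or_site
    res = structure.find_residue(cid, number, icode)
    return cid, structure.chains[cid].index(res)


# --------------------------------------------------------------------------
# energy terms
# --------------------------------------------------------------------------

def vdw_site_all(structure: ComplexStructure, site) -> float:
    """Lennard-Jones energy between the site residue and every atom within
    10 A of it (1-2/1-3 covalent pairs across the peptide links excluded)."""
    pos, _q, rmin, eps, resk = _atom_table(structure)
    cid, ri = _site_index(structure, site)
    site_mask = np.array([k == (cid, ri) for k in resk])
    if not site_mask.any():
        raise StructureError("site residue has no atoms")
    excluded = _link_exclusions(structure, resk, cid, ri)
    si = np.nonzero(site_mask)[0]
    oi = np.nonzero(~site_mask)[0]
    d = np.sqrt(((pos[si][:, None, :] - pos[oi][None, :, :]) ** 2).sum(-1))
    e = 0.0
    within = d <= SITE_CUTOFF
    for a in range(len(si)):
        js = np.nonzero(within[a])[0]
        if not len(js):
            continue
        keep = np.array([(min(si[a], oi[j]), max(si[a], oi[j])) not in excluded
                         for j in js])
        js = js[keep]
        r = np.maximum(d[a, js], 1e-6)
        rm = rmin[si[a]] + rmin[oi[js]]
        ee = np.sqrt(eps[si[a]] * eps[oi[js]])
        sr6 = (rm / r) ** 6
        e += float(np.sum(ee * (sr6 ** 2 - 2.0 * sr6)))
    return e


def _link_exclusions(structure, resk, cid, ri) -> set:
    """1-2/1-3 pairs between the site residue and its chain neighbours."""
    from .forcefield import build_topology
    top = build_topology(structure)
    site_atoms = {i for i, k in enumerate(resk) if k == (cid, ri)}
    return {(i, j) for (i, j) in top.excluded
            if (i in site_atoms) != (j in site_atoms)}


def elec_p1p2(structure: ComplexStructure) -> float:
    """Coulomb (eps=1) energy between the partners, atom pairs within 10 A."""
    if not structure.partner1 or not structure.partner2:
        raise StructureError("partners not assigned")
    pos, q, _rm, _e, resk = _atom_table(structure)
    p1 = np.array([k[0] in structure.partner1 for k in resk])
    i1 = np.nonzero(p1)[0]
    i2 = np.nonzero(~p1)[0]
    tree = cKDTree(pos[i2])
    e = 0.0
    for a in i1:
        js = tree.query_ball_point(pos[a], SITE_CUTOFF)
        if not js:
            continue
        r = np.linalg.norm(pos[i2[js]] - pos[a], axis=1)
        e += float(np.sum(COULOMB_CONSTANT * q[a] * q[i2[js]]
                          / np.maximum(r, 1e-6)))
    return e


def binding_polar_solvation(structure: ComplexStructure,
                            settings: PBSettings = PBSettings()) -> float:
    """dG_solv = G_com - G_p1 - G_p2 (kcal/mol), rigid partner extraction."""
    if not structure.partner1 or not structure.partner2:
        raise StructureError("partners not assigned")
    parameterize(structure)

    def arrays(chain_ids):
        pos, q, rad = [], [], []
        for cid in chain_ids:
            for res in structure.chains[cid]:
                for a in res.atoms:
                    pos.append(a.position)
                    q.append(a.partial_charge)
                    rad.append(a.pb_radius)
        return np.asarray(pos), np.asarray(q), np.asarray(rad)

    g = {}
    for key, cids in (("com", structure.chain_ids),
                      ("p1", structure.partner1),
                      ("p2", structure.partner2)):
        pos, q, rad = arrays(cids)
        g[key] = pb_solvation_energy(pos, q, rad, settings)
    return g["com"] - g["p1"] - g["p2"]


def hbonds_p1p2(structure: ComplexStructure,
                criteria: HBondCriteria = HBondCriteria()) -> int:
    return count_hbonds(structure, chain_selector(structure.partner1),
                        chain_selector(structure.partner2), criteria)


def hbonds_site_all(structure: ComplexStructure, site,
                    criteria: HBondCriteria = HBondCriteria()) -> int:
    cid, ri = _site_index(structure, site)
    sel = residue_selector(cid, ri)
    return count_hbonds(structure, sel, complement_selector(sel), criteria)


def sasa_ratio_com_p2(structure: ComplexStructure) -> float:
    a_com = total_sasa(structure)
    a_p2 = total_sasa(structure, chain_ids=structure.partner2)
    return a_com / a_p2


def interface_flag(structure: ComplexStructure, site) -> int:
    """1 iff the residue loses solvent accessibility upon binding
    (SASA in complex < SASA in its unbound partner, strict)."""
    cid, ri = _site_index(structure, site)
    res = structure.chains[cid][ri]
    key = (cid, res.number, res.icode)
    in_complex = residue_sasa(structure)[key]
    partner = (structure.partner1 if cid in structure.partner1
               else structure.partner2)
    unbound = residue_sasa(structure, chain_ids=partner)[key]
    return int(in_complex < unbound - INTERFACE_SASA_TOL)


# --------------------------------------------------------------------------
# fold potential
# --------------------------------------------------------------------------

@lru_cache(maxsize=1)
def load_contact_potential() -> dict:
    """Synthetic stand-in pairwise contact potential, 20x20 symmetric,
    keyed by one-letter amino-acid pairs."""
    text = (files("dnabind") / "data"
            / "synthetic_contact_potential.txt").read_text()
    rows = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = rows[0].split()
    table = {}
    for ln in rows[1:]:
        parts = ln.split()
        a = parts[0]
        for b, v in zip(header, parts[1:]):
            table[(a, b)] = float(v)
    for (a, b), v in list(table.items()):
        assert abs(table[(b, a)] - v) < 1e-9, "matrix must be symmetric"
    return table


def _contact_anchor(res):
    """Side-chain anchor for contact counting: CB, or CA for glycine."""
    name = "CA" if res.name == "GLY" else "CB"
    return res.atom(name).position if res.has_atom(name) else None


def fold_potential_delta(wild: ComplexStructure, mutation: Mutation,
                         table: dict | None = None) -> float:
    """Contact-potential change at the site: sum over protein residues j in
    contact (anchor distance <= 6.5 A, j != site) of M(mut, aa_j) - M(wt, aa_j)."""
    table = table or load_contact_potential()
    cid, ri = _site_index(structure=wild, mutation_or_site=mutation)
    site = wild.chains[cid][ri]
    anchor = _contact_anchor(site)
    if anchor is None:
        raise StructureError(f"site {site.label} lacks a side-chain anchor")
    delta = 0.0
    for cid2 in wild.partner1 or wild.chain_ids:
        for rj, res in enumerate(wild.chains[cid2]):
            if res.kind != "protein" or (cid2, rj) == (cid, ri):
                continue
            other = _contact_anchor(res)
            if other is None:
                continue
            if np.linalg.norm(anchor - other) <= CONTACT_CUTOFF:
                aa_j = AMINO_ACIDS[res.name]
                delta += (table[(mutation.mut_aa, aa_j)]
                          - table[(mutation.wt_aa, aa_j)])
    return delta


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def assemble_features(wild_min: ComplexStructure, mut_min: ComplexStructure,
                      mutation: Mutation,
                      pb_settings: PBSettings = PBSettings(),
                      criteria: HBondCriteria = HBondCriteria(),
                      ) -> FeatureVector:
    """All nine features from minimized wild-type and mutant complexes."""
    site = (mutation.chain_id, mutation.residue_number, mutation.icode)
    return FeatureVector(
        sa_ratio_com_p2=sasa_ratio_com_p2(wild_min),
        ddg_solv=(binding_polar_solvation(mut_min, pb_settings)
                  - binding_polar_solvation(wild_min, pb_settings)),
        d_nhbond_p1p2=float(hbonds_p1p2(mut_min, criteria)
                            - hbonds_p1p2(wild_min, criteria)),
        elec_mut_p1p2=elec_p1p2(mut_min),
        nhbond_wt_site_all=float(hbonds_site_all(wild_min, site, criteria)),
        l_mut=float(len(wild_min.chains[mutation.chain_id])),
        dd_evdw_site_all=(vdw_site_all(mut_min, site)
                          - vdw_site_all(wild_min, site)),
        d_e_fold=fold_potential_delta(wild_min, mutation),
        location_mut=float(interface_flag(wild_min, site)),
    )
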