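"""Building mutant complexes by single side-chain replacement.

The mutated residue keeps its backbone; the new side chain comes from the
ideal residue template posed on the backbone (N/CA/C superposition) and is
sampled over a small backbone-independent rotamer library (coarse chi grid
at -60/60/180 degrees per rotatable bond, weighted toward the staggered
trans/gauche- states).  The rotamer with the lowest repulsive Lennard-Jones
clash score against all atoms within 10 A wins; ties break first to the
higher prior weight, then to the lower rotamer index, so the build is fully
deterministic.  Neighbouring side chains are not repacked — residual strain
is relaxed by the downstream restrained minimization.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

import numpy as np

from .geometry import kabsch, apply_rigid, dihedral, rotation_about_axis
from .params import load_parameter_table
from .structure import (
    AtomRecord, ComplexStructure, Mutation, StructureError, _is_backbone,
)
from .templates import CHI_ATOMS, ONE_TO_THREE, AMINO_ACIDS, get_template

CLASH_CUTOFF = 10.0    # A, context radius for the clash score
_BACKBONE_KEEP = ("N", "CA", "C", "O")
# chi values (deg) and prior weights, staggered rotamer states
_CHI_VALUES = (180.0, -60.0, 60.0)
_CHI_WEIGHTS = (0.45, 0.35, 0.20)


@dataclass(frozen=True)
class Rotamer:
    chis: tuple[float, ...]    # degrees
    weight: float


@dataclass(frozen=True)
class RotamerLibrary:
    """Per amino acid: list of side-chain dihedral tuples with weights."""
    rotamers: dict

    def for_residue(self, aa3: str) -> list[Rotamer]:
        return self.rotamers[aa3]


@lru_cache(maxsize=1)
def default_library() -> RotamerLibrary:
    """Coarse staggered chi grid; >= 3 rotamers per rotatable residue."""
    lib = {}
    for aa3, chis in CHI_ATOMS.items():
        if not chis:
            lib[aa3] = [Rotamer((), 1.0)]
            continue
        rots = []
        for combo in product(range(len(_CHI_VALUES)), repeat=len(chis)):
            vals = tuple(_CHI_VALUES[k] for k in combo)
            w = float(np.prod([_CHI_WEIGHTS[k] for k in combo]))
            rots.append(Rotamer(vals, w))
        lib[aa3] = rots
    return RotamerLibrary(lib)


def _downstream_atoms(tpl, chi_quad) -> list[str]:
    """Heavy atoms that move when the chi bond (b-c) rotates: the connected
    component containing c after deleting edge (b, c), minus c itself."""
    _a, b, c, _d = chi_quad
    adj: dict[str, set] = {}
    for (x, y) in tpl.bonds:
        adj.setdefault(x, set()).add(y)
        adj.setdefault(y, set()).add(x)
    adj[b].discard(c)
    adj[c].discard(b)
    seen, stack = {c}, [c]
    while stack:
        for nxt in adj.get(stack.pop(), ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    seen.discard(c)
    return sorted(seen)


def _pose_side_chain(res, aa3: str, rotamer: Rotamer) -> dict:
    """Heavy-atom coordinates of the replacement residue: original backbone
    plus template side chain at the rotamer's chi angles."""
    tpl = get_template(aa3)
    src = np.array([tpl.positions[x] for x in ("N", "CA", "C")])
    tgt = np.array([res.atom(x).position for x in ("N", "CA", "C")])
    r, t = kabsch(src, tgt)
    coords = {n: res.atom(n).position.copy()
              for n in _BACKBONE_KEEP if res.has_atom(n)}
    for name in tpl.atom_names:
        if name not in coords:
            coords[name] = apply_rigid(tpl.positions[name], r, t)
    for quad, chi_target in zip(CHI_ATOMS[aa3], rotamer.chis):
        a, b, c, d = (coords[x] for x in quad)
        current = dihedral(a, b, c, d)
        rot = rotation_about_axis(c - b, np.radians(chi_target) - current)
        for name in _downstream_atoms(tpl, quad):
            if name in coords:
                coords[name] = b + rot @ (coords[name] - b)
    return coords


def _clash_score(coords: dict, aa3: str, context_pos: np.ndarray,
                 context_rmin: np.ndarray, context_eps: np.ndarray) -> float:
    """Repulsive-only LJ score of the posed side chain against its context."""
    table = load_parameter_table()
    tpl = get_template(aa3)
    moving = [n for n in tpl.atom_names if n not in _BACKBONE_KEEP]
    if not moving or not len(context_pos):
        return 0.0
    pos = np.array([coords[n] for n in moving])
    rmin = np.array([table[(aa3, n)][1] for n in moving])
    eps = np.array([table[(aa3, n)][2] for n in moving])
    d = np.sqrt(((pos[:, None, :] - context_pos[None, :, :]) ** 2).sum(-1))
    within = d <= CLASH_CUTOFF
    if not within.any():
        return 0.0
    rm = rmin[:, None] + context_rmin[None, :]
    ee = np.sqrt(eps[:, None] * context_eps[None, :])
    ratio = np.where(within, rm / np.maximum(d, 1e-6), 0.0)
    return float(np.sum(ee * ratio ** 12))


def build_mutant(wild: ComplexStructure, mutation: Mutation,
                 library: RotamerLibrary | None = None) -> ComplexStructure:
    """Wild-type complex with one side chain replaced (heavy atoms only at
    the mutated site; re-protonate afterwards).

    A self-mutation returns an identical copy.  The wild-type identity of
    the addressed residue is verified and mismatches are reported with the
    residue actually found.
    """
    if mutation.mut_aa not in ONE_TO_THREE:
        raise StructureError(f"unknown target amino acid {mutation.mut_aa!r}")
    res = wild.find_residue(mutation.chain_id, mutation.residue_number,
                            mutation.icode)
    if res.kind != "protein":
        raise StructureError(f"residue {res.label} is not an amino acid")
    found = AMINO_ACIDS[res.name]
    if found != mutation.wt_aa:
        raise StructureError(
            f"wild-type mismatch at {res.label}: expected {mutation.wt_aa}, "
            f"found {found}")
    for bb in ("N", "CA", "C"):
        if not res.has_atom(bb):
            raise StructureError(
                f"site {res.label} lacks backbone atom {bb}")

    out = wild.copy()
    if mutation.wt_aa == mutation.mut_aa:
        return out

    aa3 = ONE_TO_THREE[mutation.mut_aa]
    library = library or default_library()
    cid = mutation.chain_id
    ri = next(i for i, r in enumerate(out.chains[cid])
              if r.number == mutation.residue_number
              and r.icode == mutation.icode)
    site = out.chains[cid][ri]

    # context: all heavy atoms outside the mutated residue
    table = load_parameter_table()
    ctx_pos, ctx_rmin, ctx_eps = [], [], []
    for cid2 in out.chain_ids:
        for rj, other in enumerate(out.chains[cid2]):
            if (cid2, rj) == (cid, ri):
                continue
            for a in other.atoms:
                if a.is_hydrogen:
                    continue
                ctx_pos.append(a.position)
                q, rm, ep, _pb = table[(other.name, a.name)]
                ctx_rmin.append(rm)
                ctx_eps.append(ep)
    ctx_pos = np.asarray(ctx_pos)
    ctx_rmin = np.asarray(ctx_rmin)
    ctx_eps = np.asarray(ctx_eps)

    best = None   # (score, -weight, index, coords)
    for idx, rot in enumerate(library.for_residue(aa3)):
        coords = _pose_side_chain(site, aa3, rot)
        score = _clash_score(coords, aa3, ctx_pos, ctx_rmin, ctx_eps)
        key = (score, -rot.weight, idx)
        if best is None or key < best[0]:
            best = (key, coords)
    coords = best[1]

    tpl = get_template(aa3)
    site.name = aa3
    site.atoms = [AtomRecord(
        name=n, element=tpl.elements[tpl.heavy_index(n)],
        position=np.asarray(coords[n], dtype=float).copy(),
        is_backbone=_is_backbone(aa3, n),
    ) for n in tpl.atom_names]
    return out
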