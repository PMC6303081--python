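"""Geometric hydrogen-bond detection.

A hydrogen bond is a donor-H...acceptor triple with the hydrogen-acceptor
distance at most 2.5 A and the donor-hydrogen-acceptor angle at least 90
degrees.  Donor and acceptor chemistry is derived from the covalent
topology: a donor is an N/O/S with a bound hydrogen; an acceptor is any
oxygen, or a nitrogen that carries no hydrogen and has at most two heavy
neighbours (pyridine-type ring nitrogens, e.g. DNA base N7/N1/N3 or the
free imidazole nitrogen).  Intra-residue triples and acceptors covalently
bonded to the donor are never counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class HBondCriteria:
    max_h_acceptor_dist: float = 2.5   # A
    min_dha_angle: float = 90.0        # degrees


_H_BOND_MAX = 1.25    # A, H-parent covalent detection
_HEAVY_BOND_MAX = 1.85


def _flatten(structure):
    pos, elem, resk, name = [], [], [], []
    for cid in structure.chain_ids:
        for ri, res in enumerate(structure.chains[cid]):
            for a in res.atoms:
                pos.append(a.position)
                elem.append(a.element)
                resk.append((cid, ri))
                name.append(a.name)
    return np.asarray(pos), np.asarray(elem), resk, name


def _covalent(pos, elem):
    """H->parent index map and heavy-atom neighbour count / H count."""
    n = len(pos)
    is_h = elem == "H"
    tree = cKDTree(pos)
    parent = np.full(n, -1, dtype=int)
    heavy_deg = np.zeros(n, dtype=int)
    n_h = np.zeros(n, dtype=int)
    pairs = tree.query_pairs(_HEAVY_BOND_MAX, output_type="ndarray")
    for i, j in pairs:
        d = np.linalg.norm(pos[i] - pos[j])
        if is_h[i] and is_h[j]:
            continue
        if is_h[i] or is_h[j]:
            h, p = (i, j) if is_h[i] else (j, i)
            if d <= _H_BOND_MAX and (
                    parent[h] < 0
                    or d < np.linalg.norm(pos[h] - pos[parent[h]])):
                parent[h] = p
        else:
            heavy_deg[i] += 1
            heavy_deg[j] += 1
    for h in np.nonzero(is_h)[0]:
        if parent[h] >= 0:
            n_h[parent[h]] += 1
    return parent, heavy_deg, n_h


def find_hbonds(structure, in_set_a, in_set_b,
                criteria: HBondCriteria = HBondCriteria()) -> list:
    """All donor-H...acceptor triples with donor in one set, acceptor in the
    other (both directions).

    ``in_set_a`` / ``in_set_b`` are predicates ``(chain_id, residue_index,
    atom_name) -> bool`` over the structure's atoms.  Returns a list of
    ``(donor_idx_key, h_name, acceptor_idx_key)`` tuples where the keys are
    ``(chain_id, residue_index, atom_name)``.  Raises if the structure
    carries no hydrogens (protonate first).
    """
    pos, elem, resk, name = _flatten(structure)
    if not (elem == "H").any():
        raise ValueError("structure has no hydrogens: add hydrogens first")
    parent, heavy_deg, n_h = _covalent(pos, elem)

    donor_h = [h for h in np.nonzero(elem == "H")[0]
               if parent[h] >= 0 and elem[parent[h]] in ("N", "O", "S")]
    acceptors = [i for i in range(len(pos))
                 if (elem[i] == "O")
                 or (elem[i] == "N" and n_h[i] == 0 and heavy_deg[i] <= 2)]
    if not donor_h or not acceptors:
        return []
    acc_arr = np.asarray(acceptors)
    tree = cKDTree(pos[acc_arr])
    keys = [(resk[i][0], resk[i][1], name[i]) for i in range(len(pos))]

    def membership(i):
        a = in_set_a(*keys[i])
        b = in_set_b(*keys[i])
        return a, b

    out = []
    for h in donor_h:
        d = parent[h]
        da, db = membership(d)
        if not (da or db):
            continue
        near = tree.query_ball_point(pos[h], criteria.max_h_acceptor_dist)
        for k in near:
            a = int(acc_arr[k])
            if a == d or resk[a] == resk[d]:
                continue
            if np.linalg.norm(pos[a] - pos[d]) <= _HEAVY_BOND_MAX:
                continue  # acceptor covalently bonded to the donor
            aa, ab = membership(a)
            if not ((da and ab) or (db and aa)):
                continue
            v1 = pos[d] - pos[h]
            v2 = pos[a] - pos[h]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            # angle D-H-A >= min_dha_angle
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) \
                    >= criteria.min_dha_angle:
                out.append((keys[d], name[h], keys[a]))
    return out


def count_hbonds(structure, in_set_a, in_set_b,
                 criteria: HBondCriteria = HBondCriteria()) -> int:
    return len(find_hbonds(structure, in_set_a, in_set_b, criteria))


def chain_selector(chain_ids):
    ids = set(chain_ids)
    return lambda cid, ri, an: cid in ids


def residue_selector(chain_id, residue_index):
    return lambda cid, ri, an: (cid, ri) == (chain_id, residue_index)


def complement_selector(selector):
    return lambda cid, ri, an: not selector(cid, ri, an)
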