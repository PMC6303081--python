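"""Generate the shipped force-field parameter table (data/ff_params.tsv).

Charges are assigned by chemically-motivated rules over the residue-template
connectivity (polar groups get fixed group charges, aliphatic/aromatic CH
units are locally neutral), then the residue total is snapped to its
canonical integer charge at neutral pH by adjusting one nonpolar buffer
carbon.  Lennard-Jones well depths/radii and Poisson-Boltzmann radii are
element-class based.  The values are internally consistent rather than a
verbatim copy of any published force field: they feed a regression that is
retrained on data produced with them.

Run from the repository root:  python scripts/make_params.py
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from dnabind.templates import AMINO_ACIDS, NUCLEOTIDES, get_template  # noqa: E402

# element-class LJ parameters: (rmin/2 [A], epsilon [kcal/mol])
LJ_BY_ELEMENT = {
    "C": (2.00, 0.070),
    "N": (1.85, 0.200),
    "O": (1.70, 0.120),
    "S": (2.00, 0.450),
    "P": (2.15, 0.585),
}
LJ_H_APOLAR = (1.34, 0.024)   # H on carbon
LJ_H_POLAR = (0.40, 0.046)    # H on N/O/S

# PB / surface radii by element (A)
PB_BY_ELEMENT = {"C": 2.0, "N": 1.7, "O": 1.6, "S": 1.9, "P": 1.9}
PB_H = 1.0

# canonical residue net charges at neutral pH
NET_CHARGE = {res: 0 for res in AMINO_ACIDS}
NET_CHARGE.update({"ARG": 1, "LYS": 1, "ASP": -1, "GLU": -1})
NET_CHARGE.update({res: -1 for res in NUCLEOTIDES})

# buffer atom absorbing the rounding residual (a nonpolar carbon)
BUFFER = {res: "CB" for res in AMINO_ACIDS}
BUFFER["GLY"] = "CA"
BUFFER.update({res: "C2'" for res in NUCLEOTIDES})

# fixed group charges that the generic rules cannot infer
SPECIAL = {
    # protein backbone
    ("*aa", "N"): -0.47, ("*aa", "H"): 0.31, ("*aa", "CA"): 0.07,
    ("*aa", "C"): 0.51, ("*aa", "O"): -0.51,
    ("GLY", "CA"): -0.02, ("PRO", "N"): -0.29, ("PRO", "CA"): 0.02,
    # lysine ammonium
    ("LYS", "NZ"): -0.30, ("LYS", "HZ1"): 0.33, ("LYS", "HZ2"): 0.33,
    ("LYS", "HZ3"): 0.33, ("LYS", "CE"): 0.21,
    # arginine guanidinium
    ("ARG", "NE"): -0.70, ("ARG", "HE"): 0.44, ("ARG", "CZ"): 0.64,
    ("ARG", "NH1"): -0.80, ("ARG", "HH11"): 0.46, ("ARG", "HH12"): 0.46,
    ("ARG", "NH2"): -0.80, ("ARG", "HH21"): 0.46, ("ARG", "HH22"): 0.46,
    ("ARG", "CD"): 0.20,
    # histidine neutral (ND1-H)
    ("HIS", "ND1"): -0.36, ("HIS", "HD1"): 0.32, ("HIS", "CG"): -0.05,
    ("HIS", "CE1"): 0.25, ("HIS", "NE2"): -0.70, ("HIS", "CD2"): 0.22,
    # methionine thioether
    ("MET", "SD"): -0.09,
    # DNA phosphate + sugar oxygens
    ("*nt", "P"): 1.50, ("*nt", "OP1"): -0.78, ("*nt", "OP2"): -0.78,
    ("*nt", "O5'"): -0.57, ("*nt", "O3'"): -0.57, ("*nt", "O4'"): -0.50,
    ("*nt", "C4'"): 0.16, ("*nt", "C1'"): 0.16,
}


def _assign_charges(res: str) -> dict[str, float]:
    tpl = get_template(res)
    heavy = list(tpl.atom_names)
    elem = dict(zip(tpl.atom_names, tpl.elements))
    nbrs = {n: set() for n in heavy}
    for a, b in tpl.bonds:
        nbrs[a].add(b)
        nbrs[b].add(a)
    h_of = {n: [] for n in heavy}
    for rule in tpl.hydrogen_rules:
        h_of[rule.parent].append(rule.name)
        elem[rule.name] = "H"

    wild = "*aa" if res in AMINO_ACIDS else "*nt"
    q: dict[str, float] = {}

    def special(atom):
        if (res, atom) in SPECIAL:
            return SPECIAL[(res, atom)]
        return SPECIAL.get((wild, atom))

    # pass 1: heavy atoms
    for a in heavy:
        s = special(a)
        if s is not None:
            q[a] = s
            continue
        e, nh = elem[a], len(h_of[a])
        heavy_nb = nbrs[a]
        if e == "O":
            if nh == 1:
                q[a] = -0.66                      # hydroxyl
            elif len(heavy_nb) == 1:
                q[a] = -0.55                      # carbonyl / carboxylate (refined below)
            else:
                q[a] = -0.40                      # ether oxygen
        elif e == "N":
            if nh == 2:
                q[a] = -0.75 if res in NUCLEOTIDES else -0.62   # amino / amide
            elif nh == 1:
                q[a] = -0.55                      # ring/amide NH
            elif len(heavy_nb) >= 3:
                q[a] = -0.30                      # substituted ring N (glycosidic)
            else:
                q[a] = -0.60                      # bare ring N acceptor
        elif e == "S":
            q[a] = -0.23 if nh else -0.09
        elif e == "C":
            q[a] = -0.09 * nh                     # locally neutral CHn
        else:
            q[a] = 0.0

    # pass 2: refine carbons attached to carbonyl/carboxylate oxygens and
    # to nitrogens (ring carbons of the nucleobases, amide/guanidinium C)
    for a in heavy:
        if elem[a] != "C" or special(a) is not None:
            continue
        bare_o = [b for b in nbrs[a]
                  if elem[b] == "O" and len(nbrs[b]) == 1 and not h_of[b]
                  and special(b) is None]
        n_nb = sum(1 for b in nbrs[a] if elem[b] == "N")
        if len(bare_o) == 2:                      # carboxylate
            q[a] = 0.62
            for b in bare_o:
                q[b] = -0.76
        elif len(bare_o) == 1:                    # carbonyl / amide C
            q[a] = 0.55
        if n_nb and not bare_o:
            q[a] += 0.35 * n_nb                   # C bonded to ring/amide N
        elif n_nb and bare_o:
            q[a] += 0.10 * n_nb                   # amide-type C, milder

    # pass 3: hydrogens
    for a in heavy:
        for h in h_of[a]:
            s = special(h)
            if s is not None:
                q[h] = s
            elif elem[a] == "C":
                q[h] = 0.09
            elif elem[a] == "O":
                q[h] = 0.43
            elif elem[a] == "S":
                q[h] = 0.16
            elif elem[a] == "N":
                nh = len(h_of[a])
                q[h] = 0.37 if nh == 1 else 0.38 if res in NUCLEOTIDES else 0.31
            else:
                q[h] = 0.09

    # snap to the canonical integer net charge: amino acids absorb the small
    # residual on the buffer carbon; nucleotides spread it over the five
    # sugar carbons so no single atom ends up strongly charged
    resid = NET_CHARGE[res] - sum(q.values())
    if res in NUCLEOTIDES:
        sugar_c = ["C1'", "C2'", "C3'", "C4'", "C5'"]
        for a in sugar_c:
            q[a] += resid / len(sugar_c)
    else:
        q[BUFFER[res]] += resid
    assert abs(sum(q.values()) - NET_CHARGE[res]) < 1e-9
    return q


def main() -> None:
    out = Path(__file__).resolve().parents[1] / "src" / "dnabind" / "data" / "ff_params.tsv"
    lines = ["# dnabind force-field parameter table v1",
             "# residue\tatom\tcharge_e\trmin_half_A\tepsilon_kcal\tpb_radius_A"]
    for res in sorted(list(AMINO_ACIDS) + list(NUCLEOTIDES)):
        tpl = get_template(res)
        q = _assign_charges(res)
        elem = dict(zip(tpl.atom_names, tpl.elements))
        parent = dict(tpl.h_parent)
        for rule in tpl.hydrogen_rules:
            elem[rule.name] = "H"
        names = list(tpl.atom_names) + [r.name for r in tpl.hydrogen_rules]
        for a in names:
            e = elem[a]
            if e == "H":
                rmin, eps = (LJ_H_POLAR if elem[parent[a]] in ("N", "O", "S")
                             else LJ_H_APOLAR)
                pb = PB_H
            else:
                rmin, eps = LJ_BY_ELEMENT[e]
                pb = PB_BY_ELEMENT[e]
            lines.append(f"{res}\t{a}\t{q[a]:.4f}\t{rmin:.3f}\t{eps:.3f}\t{pb:.2f}")
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out} ({len(lines) - 2} atom entries)")


if __name__ == "__main__":
    main()
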