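"""PDB parsing/writing, partner assignment and hydrogen completion."""

import numpy as np
import pytest

from dnabind.structure import (
    StructureError, add_hydrogens, assign_partners, compute_interface_area,
    parse_structure, write_structure, Mutation,
)
from dnabind.synthetic import build_bdna, build_peptide
from dnabind.templates import get_template


def _merge(pep, dna):
    chains = dict(pep.chains)
    chains.update(dna.chains)
    out = pep.copy()
    out.chains = chains
    return out


def test_write_parse_roundtrip(toy_complex):
    text = write_structure(toy_complex)
    back = parse_structure(text)
    assert back.chain_ids == toy_complex.chain_ids
    for cid in toy_complex.chain_ids:
        a = toy_complex.chains[cid]
        b = back.chains[cid]
        assert [r.name for r in a] == [r.name for r in b]
        assert [r.number for r in a] == [r.number for r in b]
        for ra, rb in zip(a, b):
            assert [x.name for x in ra.atoms] == [x.name for x in rb.atoms]
            pa = np.array([x.position for x in ra.atoms])
            pb = np.array([x.position for x in rb.atoms])
            assert np.abs(pa - pb).max() < 1e-3 + 1e-9


def test_single_chain_rejected():
    pep = build_peptide("GAS")
    text = write_structure(pep)
    with pytest.raises(StructureError, match="at least two chains"):
        parse_structure(text)


def test_multi_model_takes_first_model():
    pep = build_peptide("GA")
    dna = build_bdna("ACGT")
    m1 = _merge(pep, dna)
    m2 = m1.copy()
    for a in m2.atoms():
        a.position = a.position + 5.0
    body1 = write_structure(m1).replace("END\n", "")
    body2 = write_structure(m2).replace("END\n", "")
    text = "MODEL        1\n" + body1 + "ENDMDL\n" \
        + "MODEL        2\n" + body2 + "ENDMDL\nEND\n"
    got = parse_structure(text)
    ref = parse_structure(write_structure(m1))
    assert np.allclose(got.coords(), ref.coords(), atol=1e-3)
    got2 = parse_structure(text, model_index=2)
    assert np.allclose(got2.coords(), ref.coords() + 5.0, atol=1e-3)


def test_empty_structure_write_rejected():
    from dnabind.structure import ComplexStructure
    with pytest.raises(StructureError):
        write_structure(ComplexStructure({}))


def test_assign_partners_validation(toy_complex):
    with pytest.raises(StructureError, match="at least one chain"):
        assign_partners(toy_complex, [], ["B", "C"])
    with pytest.raises(StructureError, match="not all protein"):
        assign_partners(toy_complex, ["B"], ["C"])
    with pytest.raises(StructureError, match="disjoint"):
        assign_partners(toy_complex, ["A"], ["A", "B"])
    two_pep = _merge(build_peptide("GAS", chain_id="A"),
                     build_peptide("KRS", chain_id="D"))
    with pytest.raises(StructureError, match="not all DNA"):
        assign_partners(two_pep, ["A"], ["D"])


def test_assign_partners_interface_gate(toy_complex):
    ok = assign_partners(toy_complex, ["A"], ["B", "C"])
    assert ok.partner1 == ("A",)
    far = toy_complex.copy()
    for res in far.chains["A"]:
        for a in res.atoms:
            a.position = a.position + np.array([50.0, 0.0, 0.0])
    with pytest.raises(StructureError, match="not interacting"):
        assign_partners(far, ["A"], ["B", "C"])


def test_interface_area_properties(toy_complex):
    area = compute_interface_area(toy_complex)
    assert area > 100.0
    # symmetric in partner order
    swapped = toy_complex.copy()
    swapped.partner1, swapped.partner2 = (toy_complex.partner2,
                                          toy_complex.partner1)
    assert compute_interface_area(swapped) == pytest.approx(area, abs=1e-6)
    # translation leaves the point sampling unchanged: exact agreement
    shifted = toy_complex.transformed(np.eye(3), np.array([11.0, -3.0, 5.0]))
    assert compute_interface_area(shifted) == pytest.approx(area, abs=1e-6)
    # rotation re-samples the spheres: agreement to the sampling resolution
    from dnabind.geometry import rotation_about_axis
    r = rotation_about_axis(np.array([1.0, 2.0, 3.0]), 0.7)
    moved = toy_complex.transformed(r, np.zeros(3))
    assert compute_interface_area(moved) == pytest.approx(area, rel=0.005)
    # separated partners bury nothing
    far = toy_complex.copy()
    for res in far.chains["A"]:
        for a in res.atoms:
            a.position = a.position + np.array([80.0, 0.0, 0.0])
    assert abs(compute_interface_area(far)) < 1e-6


def test_add_hydrogens_counts_and_idempotence():
    pep = build_peptide("GASV")
    dna = build_bdna("ACGT")
    bare = _merge(pep, dna)
    prot = add_hydrogens(bare)
    # per-residue counts match the template hydrogen sets (internal residues;
    # the backbone amide H of residue 1 has no preceding carbonyl reference)
    for res in prot.chains["A"][1:]:
        tpl = get_template(res.name)
        n_h = sum(1 for a in res.atoms if a.is_hydrogen)
        assert n_h == tpl.n_hydrogens
    again = add_hydrogens(prot)
    assert again.n_atoms == prot.n_atoms
    # heavy atoms never move
    h1 = np.array([a.position for a in prot.atoms() if not a.is_hydrogen])
    h2 = np.array([a.position for a in again.atoms() if not a.is_hydrogen])
    assert np.array_equal(h1, h2)


def test_add_hydrogens_unknown_residue_rejected():
    pep = build_peptide("GAS")
    bad = pep.copy()
    bad.chains["A"][1].name = "XXX"
    with pytest.raises(KeyError, match="XXX"):
        add_hydrogens(bad)


def test_nonstandard_residues_dropped(toy_complex):
    text = write_structure(toy_complex)
    hoh = ("HETATM99999  O   HOH A 999      99.000  99.000  99.000"
           "  1.00  0.00           O")
    text = text.replace("END", hoh + "\nEND")
    parsed = parse_structure(text)
    assert all(res.name != "HOH" for res in parsed.residues())


def test_altloc_highest_occupancy():
    pep = build_peptide("GA")
    dna = build_bdna("ACGT")
    text = write_structure(_merge(pep, dna))
    lines = [ln for ln in text.splitlines() if ln.startswith(("ATOM", "TER"))]
    out, done = [], False
    for ln in lines:
        if (not done and ln.startswith("ATOM")
                and ln[12:16].strip() == "CA" and ln[21] == "A"):
            a = ln[:16] + "A" + ln[17:54] + "  0.30" + ln[60:]
            b = ln[:16] + "B" + ln[17:30] + f"{float(ln[30:38]) + 2.0:8.3f}" \
                + ln[38:54] + "  0.70" + ln[60:]
            out.extend([a, b])
            done = True
        else:
            out.append(ln)
    parsed = parse_structure("\n".join(out) + "\nEND\n")
    ca = parsed.chains["A"][0].atom("CA")
    orig = _merge(pep, dna).chains["A"][0].atom("CA").position
    assert ca.position[0] == pytest.approx(orig[0] + 2.0, abs=1e-3)


def test_mutation_parsing():
    m = Mutation.parse("A R 124 A")
    assert (m.chain_id, m.wt_aa, m.residue_number, m.mut_aa) == \
        ("A", "R", 124, "A")
    m2 = Mutation.parse("B:K30G")
    assert (m2.chain_id, m2.wt_aa, m2.residue_number, m2.mut_aa) == \
        ("B", "K", 30, "G")
    with pytest.raises(ValueError):
        Mutation.parse("A X 124 A")
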