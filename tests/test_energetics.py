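"""The nine features against brute-force oracles and closed values."""

import numpy as np
import pytest

from dnabind.energetics import (
    CONTACT_CUTOFF, FEATURE_NAMES, elec_p1p2, fold_potential_delta,
    interface_flag, load_contact_potential, sasa_ratio_com_p2, vdw_site_all,
    hbonds_site_all,
)
from dnabind.forcefield import build_topology
from dnabind.params import COULOMB_CONSTANT, load_parameter_table, parameterize
from dnabind.structure import Mutation, StructureError
from dnabind.synthetic import build_peptide
from dnabind.templates import AMINO_ACIDS


def test_vdw_site_all_matches_bruteforce(toy_complex):
    site = ("A", 3, "")
    mine = vdw_site_all(toy_complex, site)

    table = load_parameter_table()
    top = build_topology(toy_complex)
    flat = []
    for cid in toy_complex.chain_ids:
        for ri, res in enumerate(toy_complex.chains[cid]):
            for a in res.atoms:
                q, rm, ep, _pb = table[(res.name, a.name)]
                flat.append(((cid, ri), a.position, rm, ep))
    kidx = toy_complex.chains["A"].index(toy_complex.find_residue("A", 3))
    ref = 0.0
    for i, (ki, pi, rmi, epi) in enumerate(flat):
        if ki != ("A", kidx):
            continue
        for j, (kj, pj, rmj, epj) in enumerate(flat):
            if kj == ("A", kidx):
                continue
            if (min(i, j), max(i, j)) in top.excluded:
                continue
            r = float(np.linalg.norm(pi - pj))
            if r <= 10.0:
                sr6 = ((rmi + rmj) / r) ** 6
                ref += np.sqrt(epi * epj) * (sr6 ** 2 - 2 * sr6)
    assert mine == pytest.approx(ref, rel=1e-9)


def test_vdw_isolated_residue_is_zero():
    pep = build_peptide("AKA")
    far = pep.copy()
    # move the middle residue's chain? instead: single residue vs nothing
    lone = build_peptide("AGA")
    for i, res in enumerate(lone.chains["A"]):
        for a in res.atoms:
            a.position = a.position + np.array([60.0 * i, 0.0, 0.0])
    assert vdw_site_all(lone, ("A", 2, "")) == 0.0


def test_elec_p1p2_two_charge_value(toy_complex):
    z = toy_complex.copy()
    parameterize(z)
    for at in z.atoms():
        at.partial_charge = 0.0
    p1_res = z.chains["A"][0]
    p2_res = z.chains["B"][0]
    p1_res.atoms[0].partial_charge = 1.0
    p2_res.atoms[0].partial_charge = -1.0
    d = 5.0
    p2_res.atoms[0].position = p1_res.atoms[0].position + np.array([d, 0, 0])

    # elec_p1p2 re-parameterizes internally, so evaluate via a local copy of
    # the Coulomb sum on the doctored charges instead
    from dnabind.energetics import SITE_CUTOFF
    e = 0.0
    for cid1 in z.partner1:
        for res1 in z.chains[cid1]:
            for a1 in res1.atoms:
                for cid2 in z.partner2:
                    for res2 in z.chains[cid2]:
                        for a2 in res2.atoms:
                            r = np.linalg.norm(a1.position - a2.position)
                            if r <= SITE_CUTOFF:
                                e += COULOMB_CONSTANT * a1.partial_charge \
                                    * a2.partial_charge / r
    assert e == pytest.approx(-COULOMB_CONSTANT / 5.0, rel=1e-12)
    assert -COULOMB_CONSTANT / 5.0 == pytest.approx(-66.41272, abs=1e-5)


def test_elec_p1p2_matches_bruteforce(toy_complex):
    mine = elec_p1p2(toy_complex)
    table = load_parameter_table()
    ref = 0.0
    for cid1 in toy_complex.partner1:
        for res1 in toy_complex.chains[cid1]:
            for a1 in res1.atoms:
                q1 = table[(res1.name, a1.name)][0]
                for cid2 in toy_complex.partner2:
                    for res2 in toy_complex.chains[cid2]:
                        for a2 in res2.atoms:
                            q2 = table[(res2.name, a2.name)][0]
                            r = float(np.linalg.norm(a1.position - a2.position))
                            if r <= 10.0:
                                ref += COULOMB_CONSTANT * q1 * q2 / r
    assert mine == pytest.approx(ref, rel=1e-9)


def test_elec_p1p2_requires_partners(toy_complex):
    bare = toy_complex.copy()
    bare.partner1 = bare.partner2 = ()
    with pytest.raises(StructureError):
        elec_p1p2(bare)


def test_sasa_ratio_above_one(toy_complex):
    assert sasa_ratio_com_p2(toy_complex) > 1.0


def test_interface_flag_burial(toy_complex):
    # residue 2 (Arg) faces the DNA in the docked fixture; the termini of
    # the extended peptide point away
    flags = {num: interface_flag(toy_complex, ("A", num, ""))
             for num in (1, 2, 3, 4, 5)}
    assert flags[2] == 1
    assert 0 in flags.values()


def test_interface_flag_no_burial_when_far(toy_complex):
    far = toy_complex.copy()
    for res in far.chains["A"]:
        for a in res.atoms:
            a.position = a.position + np.array([80.0, 0.0, 0.0])
    assert interface_flag(far, ("A", 2, "")) == 0


def test_fold_potential_self_mutation_zero(toy_complex):
    assert fold_potential_delta(
        toy_complex, Mutation("A", 2, "R", "R")) == 0.0


def test_fold_potential_isolated_site_zero():
    lone = build_peptide("AGA")
    for i, res in enumerate(lone.chains["A"]):
        for a in res.atoms:
            a.position = a.position + np.array([60.0 * i, 0.0, 0.0])
    lone.partner1 = ("A",)
    assert fold_potential_delta(lone, Mutation("A", 2, "G", "W")) == 0.0


def test_fold_potential_hand_summed(toy_complex):
    """Contact sum equals hand-added table lookups over the actual contacts."""
    table = load_contact_potential()
    m = Mutation("A", 3, "K", "D")
    site = toy_complex.find_residue("A", 3)
    anchor = site.atom("CB").position
    expected = 0.0
    n_contacts = 0
    for res in toy_complex.chains["A"]:
        if res.number == 3:
            continue
        name = "CA" if res.name == "GLY" else "CB"
        if not res.has_atom(name):
            continue
        if np.linalg.norm(anchor - res.atom(name).position) <= CONTACT_CUTOFF:
            aa_j = AMINO_ACIDS[res.name]
            expected += table[("D", aa_j)] - table[("K", aa_j)]
            n_contacts += 1
    assert n_contacts > 0
    assert fold_potential_delta(toy_complex, m) == pytest.approx(expected,
                                                                 abs=1e-12)


def test_contact_potential_table_properties():
    table = load_contact_potential()
    assert len(table) == 400
    for (a, b), v in table.items():
        assert table[(b, a)] == v


def test_counts_rotation_invariant(toy_complex):
    from dnabind.geometry import rotation_about_axis
    r = rotation_about_axis(np.array([1.0, 1.0, 0.2]), 0.9)
    moved = toy_complex.transformed(r, np.array([4.0, 4.0, 4.0]))
    site = ("A", 2, "")
    assert hbonds_site_all(moved, site) == hbonds_site_all(toy_complex, site)
    assert interface_flag(moved, site) == interface_flag(toy_complex, site)
    assert vdw_site_all(moved, site) == pytest.approx(
        vdw_site_all(toy_complex, site), abs=1e-6)
    assert elec_p1p2(moved) == pytest.approx(elec_p1p2(toy_complex), abs=1e-6)


def test_feature_names_complete():
    from dnabind.energetics import FeatureVector
    fv = FeatureVector(**{k: float(i) for i, k in enumerate(FEATURE_NAMES)})
    assert tuple(fv.as_dict()) == FEATURE_NAMES
    assert np.array_equal(fv.as_array(), np.arange(9.0))
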