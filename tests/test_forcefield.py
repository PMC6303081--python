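"""Molecular-mechanics energies, gradients and the restrained minimizer."""

import numpy as np
import pytest

from dnabind.forcefield import (
    EnergyBreakdown, MinimizationSettings, Topology, build_topology,
    energy_and_gradient, minimize, total_energy,
)
from dnabind.params import COULOMB_CONSTANT
from dnabind.structure import add_hydrogens
from dnabind.mutator import build_mutant
from dnabind.structure import Mutation


def pair_topology(q=(0.0, 0.0), rmin_half=(1.7, 1.7), eps=(0.2, 0.2)):
    return Topology(
        charges=np.array(q, float), rmin_half=np.array(rmin_half, float),
        epsilon=np.array(eps, float),
        backbone_mask=np.zeros(2, bool), hydrogen_mask=np.zeros(2, bool),
        bonds=np.zeros((0, 2), int), bond_r0=np.zeros(0), bond_k=np.zeros(0),
        angles=np.zeros((0, 3), int), angle_theta0=np.zeros(0),
    )


class _Points:
    """Minimal coordinate holder satisfying the minimizer's interface."""

    def __init__(self, pos):
        self._pos = np.asarray(pos, float)

    def coords(self):
        return self._pos.copy()

    def set_coords(self, pos):
        self._pos = np.asarray(pos, float).copy()

    def copy(self):
        return _Points(self._pos)


def test_lj_pair_minimum_energy():
    top = pair_topology()
    rmin_ij = 3.4
    pos = np.array([[0.0, 0, 0], [rmin_ij, 0, 0]])
    e, g = energy_and_gradient(pos, top, MinimizationSettings())
    assert e.vdw == pytest.approx(-0.2, rel=1e-12)     # -eps_ij at R_min
    assert np.abs(g).max() < 1e-9


def test_coulomb_pair_value():
    top = pair_topology(q=(1.0, 1.0), eps=(0.0, 0.0))
    pos = np.array([[0.0, 0, 0], [3.320636, 0, 0]])
    e, _ = energy_and_gradient(pos, top, MinimizationSettings())
    assert e.elec == pytest.approx(100.0, abs=1e-9)
    pos2 = np.array([[0.0, 0, 0], [5.0, 0, 0]])
    top2 = pair_topology(q=(1.0, -1.0), eps=(0.0, 0.0))
    e2, _ = energy_and_gradient(pos2, top2, MinimizationSettings())
    assert e2.elec == pytest.approx(-COULOMB_CONSTANT / 5.0, rel=1e-12)


def test_cutoff_equals_bruteforce(rng):
    n = 60
    pos = rng.uniform(0, 25, size=(n, 3))
    q = rng.normal(0, 0.3, n)
    rm = rng.uniform(1.2, 2.0, n)
    ep = rng.uniform(0.02, 0.4, n)
    top = Topology(
        charges=q, rmin_half=rm, epsilon=ep,
        backbone_mask=np.zeros(n, bool), hydrogen_mask=np.zeros(n, bool),
        bonds=np.zeros((0, 2), int), bond_r0=np.zeros(0), bond_k=np.zeros(0),
        angles=np.zeros((0, 3), int), angle_theta0=np.zeros(0),
    )
    settings = MinimizationSettings()
    e, _ = energy_and_gradient(pos, top, settings)
    vdw = elec = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            r = np.linalg.norm(pos[i] - pos[j])
            if r > settings.nonbonded_cutoff:
                continue
            sr6 = ((rm[i] + rm[j]) / r) ** 6
            vdw += np.sqrt(ep[i] * ep[j]) * (sr6 ** 2 - 2 * sr6)
            elec += COULOMB_CONSTANT * q[i] * q[j] / r
    assert e.vdw == pytest.approx(vdw, rel=1e-10)
    assert e.elec == pytest.approx(elec, rel=1e-10)


def test_restraint_zero_at_reference(toy_complex):
    e = total_energy(toy_complex,
                     reference_positions=toy_complex.coords())
    assert e.restraint == 0.0
    assert e.total == pytest.approx(e.bonded + e.vdw + e.elec + e.restraint,
                                    rel=1e-12)


def test_energy_rigid_motion_invariance(toy_complex):
    from dnabind.geometry import rotation_about_axis
    e0 = total_energy(toy_complex)
    r = rotation_about_axis(np.array([0.3, -1.0, 0.5]), 1.1)
    moved = toy_complex.transformed(r, np.array([7.0, 8.0, -9.0]))
    e1 = total_energy(moved)
    assert e1.total == pytest.approx(e0.total, abs=1e-3)


def test_gradient_matches_finite_differences(rng):
    n = 8
    pos = rng.uniform(0, 6, size=(n, 3))
    top = Topology(
        charges=rng.normal(0, 0.2, n), rmin_half=np.full(n, 1.5),
        epsilon=np.full(n, 0.1),
        backbone_mask=np.zeros(n, bool), hydrogen_mask=np.zeros(n, bool),
        bonds=np.array([[0, 1], [1, 2]]), bond_r0=np.array([1.5, 1.5]),
        bond_k=np.array([300.0, 300.0]),
        angles=np.array([[0, 1, 2]]), angle_theta0=np.array([1.9]),
        excluded={(0, 1), (1, 2), (0, 2)},
    )
    settings = MinimizationSettings()
    _, g = energy_and_gradient(pos, top, settings)
    h = 1e-6
    for (i, d) in [(0, 0), (1, 2), (3, 1), (7, 0)]:
        p1 = pos.copy()
        p1[i, d] += h
        p2 = pos.copy()
        p2[i, d] -= h
        e1, _ = energy_and_gradient(p1, top, settings)
        e2, _ = energy_and_gradient(p2, top, settings)
        assert g[i, d] == pytest.approx((e1.total - e2.total) / (2 * h),
                                        rel=1e-4, abs=1e-5)


def test_lj_dimer_relaxes_to_well_depth():
    top = pair_topology()
    start = _Points(np.array([[0.0, 0, 0], [0.9 * 3.4, 0, 0]]))
    out, trace = minimize(start, MinimizationSettings(gradient_tol=1e-6),
                          topology=top)
    assert trace == sorted(trace, reverse=True)
    assert trace[-1] == pytest.approx(-0.2, rel=0.01)
    d = np.linalg.norm(out.coords()[1] - out.coords()[0])
    assert d == pytest.approx(3.4, rel=0.01)


def test_already_minimized_structure_unchanged():
    top = pair_topology()
    start = _Points(np.array([[0.0, 0, 0], [3.4, 0, 0]]))
    out, trace = minimize(start, topology=top)
    assert np.array_equal(out.coords(), start.coords())
    assert len(trace) == 1


def test_minimization_monotone_and_backbone_restrained(wild_min):
    """A bulky substitution introduces clashes; minimization must lower the
    energy monotonically while restrained backbone atoms barely move."""
    clashed = add_hydrogens(build_mutant(wild_min, Mutation("A", 2, "R", "W")))
    out, trace = minimize(clashed, MinimizationSettings(gradient_tol=1e-4))
    assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))
    assert trace[-1] < trace[0]
    bb0 = np.array([a.position for a in clashed.atoms() if a.is_backbone])
    bb1 = np.array([a.position for a in out.atoms() if a.is_backbone])
    rmsd = float(np.sqrt(((bb0 - bb1) ** 2).sum(1).mean()))
    assert rmsd < 0.5


def test_longer_minimization_never_raises_final_energy(toy_complex):
    _, t40 = minimize(toy_complex, MinimizationSettings(n_steps=40))
    _, t100 = minimize(toy_complex, MinimizationSettings(n_steps=100))
    assert t100[-1] <= t40[-1] + 1e-9


def test_unparameterized_atom_rejected(toy_complex):
    broken = toy_complex.copy()
    broken.chains["A"][0].atoms[0].name = "XQ"
    from dnabind.params import ParameterError
    with pytest.raises(ParameterError, match="XQ"):
        build_topology(broken)


def test_settings_validation():
    with pytest.raises(ValueError):
        MinimizationSettings(n_steps=0)
    with pytest.raises(ValueError):
        MinimizationSettings(restraint_k=-1.0)


def test_energy_breakdown_total():
    e = EnergyBreakdown(1.0, 2.0, -0.5, 0.25)
    assert e.total == pytest.approx(2.75, rel=1e-12)
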