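"""Simplified molecular-mechanics energy and restrained minimization.

The energy is CHARMM-shaped: harmonic bonds and angles (equilibrium values
measured from the ideal residue templates), 6-12 Lennard-Jones with
Lorentz-Berthelot-style combination (R_min,ij = rmin_half_i + rmin_half_j,
eps_ij = sqrt(eps_i * eps_j)), and gas-phase Coulomb (dielectric 1) with the
CHARMM electrostatic constant.  Nonbonded interactions are truncated at a
12 A cutoff and 1-2/1-3 bonded pairs are excluded.  Hydrogen-containing
bonds are kept rigid by stiff harmonic terms rather than constraint
algorithms, which is equivalent for gradient descent.

Minimization is Polak-Ribiere conjugate gradient with a backtracking line
search, 100 steps by default, with harmonic positional restraints (5 kcal
mol^-1 A^-2) on the backbone atoms of all residues (protein N/CA/C/O and
the DNA sugar-phosphate backbone).  Severe steric clashes are pre-relieved
with a few capped steepest-descent moves so that rotamer-built mutants
always start from a finite energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import angle as _angle3
from .params import COULOMB_CONSTANT, parameterize
from .templates import get_template

# equilibrium geometry of inter-residue links (deg where angular)
PEPTIDE_BOND = ("C", "N", 1.329)
PHOSPHODIESTER_BOND = ("O3'", "P", 1.607)
LINK_ANGLES = {
    ("CA", "C", "N"): 116.7, ("O", "C", "N"): 122.5,
    ("C", "N", "CA"): 121.5, ("C", "N", "H"): 119.0, ("C", "N", "CD"): 127.0,
    ("C3'", "O3'", "P"): 119.7, ("O3'", "P", "O5'"): 104.0,
    ("O3'", "P", "OP1"): 108.1, ("O3'", "P", "OP2"): 108.3,
}

K_BOND_HEAVY = 300.0   # kcal/mol/A^2
K_BOND_H = 350.0       # stiff, replaces bond constraints
K_ANGLE = 50.0         # kcal/mol/rad^2


@dataclass
class MinimizationSettings:
    """Defaults mirror the optimization protocol of the prediction method."""
    n_steps: int = 100
    restraint_k: float = 5.0          # kcal/mol/A^2 on backbone atoms
    nonbonded_cutoff: float = 12.0    # A
    gradient_tol: float = 0.05        # RMS gradient (kcal/mol/A) for early stop
    max_step: float = 0.25            # A, per-atom displacement cap per CG step

    def __post_init__(self):
        if min(self.n_steps, self.restraint_k, self.nonbonded_cutoff) <= 0:
            raise ValueError("minimization settings must be positive")


@dataclass
class EnergyBreakdown:
    bonded: float
    vdw: float
    elec: float
    restraint: float

    @property
    def total(self) -> float:
        return self.bonded + self.vdw + self.elec + self.restraint


@dataclass
class Topology:
    """Flat per-atom arrays plus bonded terms for one structure."""
    charges: np.ndarray
    rmin_half: np.ndarray
    epsilon: np.ndarray
    backbone_mask: np.ndarray
    hydrogen_mask: np.ndarray
    bonds: np.ndarray          # (nb, 2) int
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angles: np.ndarray         # (na, 3) int, vertex in the middle
    angle_theta0: np.ndarray
    excluded: set = field(default_factory=set)   # frozen {(i, j), i<j} 1-2/1-3
    labels: list = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.charges)


def build_topology(structure) -> Topology:
    """Parameterize the structure and enumerate bonds/angles/exclusions."""
    parameterize(structure)
    index: dict[tuple, int] = {}
    charges, rmin, eps, bb, hyd, labels = [], [], [], [], [], []
    i = 0
    for cid in structure.chain_ids:
        for ri, res in enumerate(structure.chains[cid]):
            for a in res.atoms:
                index[(cid, ri, a.name)] = i
                charges.append(a.partial_charge)
                rmin.append(a.lj_rmin_half)
                eps.append(a.lj_epsilon)
                bb.append(a.is_backbone)
                hyd.append(a.is_hydrogen)
                labels.append(f"{res.label}/{a.name}")
                i += 1

    bonds, r0s, ks = [], [], []

    def add_bond(ia, ib, r0, k):
        bonds.append((ia, ib))
        r0s.append(r0)
        ks.append(k)

    for cid in structure.chain_ids:
        residues = structure.chains[cid]
        for ri, res in enumerate(residues):
            tpl = get_template(res.name)
            present = {a.name for a in res.atoms}
            for (na, nb) in tpl.bonds:
                if na in present and nb in present:
                    r0 = float(np.linalg.norm(
                        tpl.positions[na] - tpl.positions[nb]))
                    add_bond(index[(cid, ri, na)], index[(cid, ri, nb)],
                             r0, K_BOND_HEAVY)
            for rule in tpl.hydrogen_rules:
                if rule.name in present and rule.parent in present:
                    add_bond(index[(cid, ri, rule.name)],
                             index[(cid, ri, rule.parent)],
                             rule.bond, K_BOND_H)
            # link to the next residue in the chain
            if ri + 1 < len(residues) and residues[ri + 1].kind == res.kind:
                nxt = residues[ri + 1]
                la, lb, lr0 = (PEPTIDE_BOND if res.kind == "protein"
                               else PHOSPHODIESTER_BOND)
                if res.has_atom(la) and nxt.has_atom(lb):
                    add_bond(index[(cid, ri, la)], index[(cid, ri + 1, lb)],
                             lr0, K_BOND_HEAVY)

    bonds_arr = np.asarray(bonds, dtype=int) if bonds else np.zeros((0, 2), int)

    # angles: every pair of bonds sharing an atom
    adjacency: dict[int, list[int]] = {}
    for (ia, ib) in bonds:
        adjacency.setdefault(ia, []).append(ib)
        adjacency.setdefault(ib, []).append(ia)
    angles, theta0 = [], []
    name_of = {v: k for k, v in index.items()}
    tpl_cache = {}
    for j, nbrs in adjacency.items():
        nbrs = sorted(nbrs)
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                ia, ik = nbrs[x], nbrs[y]
                angles.append((ia, j, ik))
                theta0.append(_equilibrium_angle(
                    structure, name_of, tpl_cache, ia, j, ik))
    angles_arr = (np.asarray(angles, dtype=int) if angles
                  else np.zeros((0, 3), int))

    excluded = set()
    for (ia, ib) in bonds:
        excluded.add((min(ia, ib), max(ia, ib)))
    for (ia, j, ik) in angles:
        excluded.add((min(ia, ik), max(ia, ik)))

    return Topology(
        charges=np.asarray(charges), rmin_half=np.asarray(rmin),
        epsilon=np.asarray(eps), backbone_mask=np.asarray(bb, bool),
        hydrogen_mask=np.asarray(hyd, bool),
        bonds=bonds_arr, bond_r0=np.asarray(r0s), bond_k=np.asarray(ks),
        angles=angles_arr, angle_theta0=np.asarray(theta0),
        excluded=excluded, labels=labels,
    )


def _equilibrium_angle(structure, name_of, tpl_cache, ia, j, ik) -> float:
    """Equilibrium angle ia-j-ik in radians.

    Measured from the ideal template when all three atoms share a residue;
    inter-residue link angles come from a small constant table, falling back
    to the as-built geometry for exotic triples.
    """
    (ca, ra, na), (cj, rj, nj), (ck, rk, nk) = \
        name_of[ia], name_of[j], name_of[ik]
    if (ca, ra) == (cj, rj) == (ck, rk):
        res = structure.chains[ca][ra]
        tpl = tpl_cache.get(res.name)
        if tpl is None:
            tpl = tpl_cache[res.name] = get_template(res.name)
        return _angle3(tpl.positions[na], tpl.positions[nj], tpl.positions[nk])
    for key in ((na, nj, nk), (nk, nj, na)):
        if key in LINK_ANGLES:
            return math.radians(LINK_ANGLES[key])
    a = structure.chains[ca][ra].atom(na).position
    b = structure.chains[cj][rj].atom(nj).position
    c = structure.chains[ck][rk].atom(nk).position
    return _angle3(a, b, c)


# --------------------------------------------------------------------------
# energy and gradient
# --------------------------------------------------------------------------

def _nonbonded_pairs(pos: np.ndarray, cutoff: float, excluded: set) -> np.ndarray:
    tree = cKDTree(pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) and excluded:
        keep = [k for k, (i, j) in enumerate(pairs)
                if (int(i), int(j)) not in excluded]
        pairs = pairs[keep]
    return pairs


def energy_and_gradient(pos: np.ndarray, top: Topology,
                        settings: MinimizationSettings,
                        reference: np.ndarray | None = None,
                        restrained: np.ndarray | None = None,
                        shift: bool = False,
                        ) -> tuple[EnergyBreakdown, np.ndarray]:
    """Total energy (kcal/mol) and Cartesian gradient (kcal/mol/A).

    With ``shift=True`` the nonbonded terms are energy-shifted to vanish at
    the cutoff (gradients inside the cutoff are unchanged).  Plain truncation
    (the default) is what the energy terms report; the continuous shifted
    form is what the minimizer descends on, so that pairs crossing the
    cutoff cannot produce jumps in its objective.
    """
    pos = np.asarray(pos, dtype=float)
    grad = np.zeros_like(pos)
    e_bonded = 0.0

    if len(top.bonds):
        vi = pos[top.bonds[:, 0]] - pos[top.bonds[:, 1]]
        r = np.linalg.norm(vi, axis=1)
        dr = r - top.bond_r0
        e_bonded += float(np.sum(top.bond_k * dr ** 2))
        f = (2.0 * top.bond_k * dr / np.maximum(r, 1e-12))[:, None] * vi
        np.add.at(grad, top.bonds[:, 0], f)
        np.add.at(grad, top.bonds[:, 1], -f)

    if len(top.angles):
        ia, jj, ik = top.angles[:, 0], top.angles[:, 1], top.angles[:, 2]
        u = pos[ia] - pos[jj]
        v = pos[ik] - pos[jj]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cos_t = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cos_t)
        dtheta = theta - top.angle_theta0
        e_bonded += float(np.sum(K_ANGLE * dtheta ** 2))
        sin_t = np.sqrt(np.maximum(1.0 - cos_t ** 2, 1e-12))
        pref = (2.0 * K_ANGLE * dtheta / (-sin_t))
        du = (v / (nu * nv)[:, None]) - (cos_t / nu ** 2)[:, None] * u
        dv = (u / (nu * nv)[:, None]) - (cos_t / nv ** 2)[:, None] * v
        np.add.at(grad, ia, pref[:, None] * du)
        np.add.at(grad, ik, pref[:, None] * dv)
        np.add.at(grad, jj, -pref[:, None] * (du + dv))

    e_vdw = e_elec = 0.0
    pairs = _nonbonded_pairs(pos, settings.nonbonded_cutoff, top.excluded)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        d = pos[i] - pos[j]
        r = np.linalg.norm(d, axis=1)
        r = np.maximum(r, 1e-6)
        rmin_ij = top.rmin_half[i] + top.rmin_half[j]
        eps_ij = np.sqrt(top.epsilon[i] * top.epsilon[j])
        sr6 = (rmin_ij / r) ** 6
        e_vdw = float(np.sum(eps_ij * (sr6 ** 2 - 2.0 * sr6)))
        qq = COULOMB_CONSTANT * top.charges[i] * top.charges[j]
        e_elec = float(np.sum(qq / r))
        if shift:
            rc = settings.nonbonded_cutoff
            src6 = (rmin_ij / rc) ** 6
            e_vdw -= float(np.sum(eps_ij * (src6 ** 2 - 2.0 * src6)))
            e_elec -= float(np.sum(qq / rc))
        dEdr = eps_ij * (-12.0 * sr6 ** 2 + 12.0 * sr6) / r - qq / r ** 2
        f = (dEdr / r)[:, None] * d
        np.add.at(grad, i, f)
        np.add.at(grad, j, -f)

    e_res = 0.0
    if reference is not None:
        mask = top.backbone_mask if restrained is None else restrained
        dx = pos[mask] - reference[mask]
        e_res = float(settings.restraint_k * np.sum(dx ** 2))
        grad[mask] += 2.0 * settings.restraint_k * dx

    return EnergyBreakdown(e_bonded, e_vdw, e_elec, e_res), grad


def total_energy(structure, settings: MinimizationSettings | None = None,
                 reference_positions: np.ndarray | None = None) -> EnergyBreakdown:
    """Energy breakdown of a parameterized, protonated structure."""
    settings = settings or MinimizationSettings()
    top = build_topology(structure)
    pos = structure.coords()
    e, _ = energy_and_gradient(pos, top, settings, reference_positions)
    return e


# --------------------------------------------------------------------------
# minimization
# --------------------------------------------------------------------------

def _relieve_clashes(pos, top, settings, reference, max_moves=60):
    """Capped steepest-descent moves until the energy is finite and tame."""
    e, g = energy_and_gradient(pos, top, settings, reference, shift=True)
    for _ in range(max_moves):
        gmax = np.abs(g).max()
        if np.isfinite(e.total) and gmax < 1e3:
            break
        step = np.clip(-g, -1.0, 1.0)
        scale = 0.05 / max(np.linalg.norm(step, axis=1).max(), 1e-12)
        trial = pos + scale * step
        e2, g2 = energy_and_gradient(trial, top, settings, reference, shift=True)
        if not np.isfinite(e2.total) or (np.isfinite(e.total) and e2.total > e.total):
            scale *= 0.2
            trial = pos + scale * step
            e2, g2 = energy_and_gradient(trial, top, settings, reference, shift=True)
            if not np.isfinite(e2.total) or (np.isfinite(e.total) and e2.total > e.total):
                break
        pos, e, g = trial, e2, g2
    return pos, e, g


def minimize(structure, settings: MinimizationSettings | None = None,
             topology: Topology | None = None):
    """Restrained conjugate-gradient minimization of a complex.

    Returns ``(minimized_structure, energy_trace)``; the trace (total energy
    after each accepted step, first element = starting energy) is
    monotonically non-increasing.  Reference positions for the backbone
    restraints are the input coordinates.
    """
    settings = settings or MinimizationSettings()
    top = topology if topology is not None else build_topology(structure)
    pos = structure.coords()
    reference = pos.copy()

    pos, e, g = _relieve_clashes(pos, top, settings, reference)
    if not np.isfinite(e.total):
        raise RuntimeError(
            "non-finite starting energy: unresolvable steric overlap")
    trace = [e.total]
    d = -g
    g_prev = g
    n = max(top.n_atoms, 1)

    for _ in range(settings.n_steps):
        rms_g = float(np.linalg.norm(g) / math.sqrt(n))
        if rms_g < settings.gradient_tol:
            break
        # cap the trial displacement
        dmax = np.linalg.norm(d, axis=1).max()
        alpha = min(1.0, settings.max_step / max(dmax, 1e-12))
        slope = float(np.sum(g * d))
        if slope >= 0.0:          # not a descent direction: restart on -g
            d = -g
            slope = -float(np.sum(g * g))
            dmax = np.linalg.norm(d, axis=1).max()
            alpha = min(1.0, settings.max_step / max(dmax, 1e-12))
        accepted = False
        for _ls in range(25):
            trial = pos + alpha * d
            e2, g2 = energy_and_gradient(trial, top, settings, reference,
                                         shift=True)
            if np.isfinite(e2.total) and e2.total <= e.total + 1e-4 * alpha * slope:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        pos, e = trial, e2
        beta = max(0.0, float(np.sum(g2 * (g2 - g_prev)) /
                              max(np.sum(g_prev * g_prev), 1e-30)))
        d = -g2 + beta * d
        g_prev = g = g2
        trace.append(e.total)

    out = structure.copy()
    out.set_coords(pos)
    return out, trace
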