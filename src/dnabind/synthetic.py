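"""Desk-scale synthetic fixtures: idealized B-DNA, docked peptide-DNA
complexes, and feature/ddG tables with known linear structure.

These generators make every stage of the pipeline testable without
downloading structures.  The DNA builder is a fiber-type model: base pairs
are placed on standard-frame positions with a 3.38 A rise and 36 deg twist
per step, Watson-Crick complementary strands antiparallel; the sugar
orientation of each nucleotide is chosen by a glycosidic-torsion scan that
best reconnects the sugar-phosphate backbone.  The geometry is idealized,
not crystal-quality: it exists so that interface burial, hydrogen bonding
and minimization have something physically sensible to act on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import kabsch, apply_rigid, place_atom, rotation_about_axis
from .structure import (
    AtomRecord, ResidueRecord, ComplexStructure, StructureError,
    assign_partners, add_hydrogens, _is_backbone,
)
from .templates import (
    get_template, ONE_TO_THREE, DNA_COMPLEMENT,
)

RISE = 3.38      # A per base pair step
TWIST = 36.0     # deg per base pair step

# standard-frame anchor points for base placement (pair dyad along x)
_C1P_STD = np.array([-2.80, 5.20, 0.0])
_NGLY_STD = _C1P_STD + 1.47 * (np.array([-1.65, 4.45, 0.0]) - _C1P_STD) \
    / np.linalg.norm(np.array([-1.65, 4.45, 0.0]) - _C1P_STD)
_GLY_N = {"DA": "N9", "DG": "N9", "DC": "N1", "DT": "N1"}
_GLY_C_NEXT = {"DA": "C4", "DG": "C4", "DC": "C2", "DT": "C2"}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one toy protein-DNA complex."""
    dna_sequence: str = "GCGATCGC"
    peptide_sequence: str = "GRKSA"
    docking_offset: float = 0.0     # extra A added to the contact distance
    seed: int = 0
    perturbation: float = 0.0       # A, Gaussian coordinate jitter

    def __post_init__(self):
        if not (4 <= len(self.dna_sequence) <= 12):
            raise ValueError("dna_sequence must be 4-12 nt")
        if not (3 <= len(self.peptide_sequence) <= 12):
            raise ValueError("peptide_sequence must be 3-12 aa")
        if any(b not in "ACGT" for b in self.dna_sequence):
            raise ValueError("dna_sequence must be over {A,C,G,T}")
        if any(a not in ONE_TO_THREE for a in self.peptide_sequence):
            raise ValueError("invalid amino acid in peptide_sequence")


# --------------------------------------------------------------------------
# B-DNA duplex
# --------------------------------------------------------------------------

def _residue_from_template(res_name, coords_by_name, chain_id, number):
    tpl = get_template(res_name)
    res = ResidueRecord(chain_id, number, "", res_name)
    for n, e in zip(tpl.atom_names, tpl.elements):
        res.atoms.append(AtomRecord(
            name=n, element=e, position=np.asarray(coords_by_name[n], float),
            is_backbone=_is_backbone(res_name, n),
        ))
    return res


def _place_base(res_name: str, mirror: bool) -> dict:
    """CCD nucleotide posed in the standard pair frame (heavy atoms).

    ``mirror`` flips the pose by a rotation of pi about the pair x-axis,
    which is how the complementary strand's base is generated.
    """
    tpl = get_template(res_name)
    pos = {n: tpl.positions[n].copy() for n in tpl.atom_names}
    ngly, cnext = _GLY_N[res_name], _GLY_C_NEXT[res_name]
    g = _NGLY_STD - _C1P_STD
    g = g / np.linalg.norm(g)
    # two candidate directions for the N->C(ring) bond; take the one that
    # swings the Watson-Crick edge toward the pair centre (origin)
    best = None
    for s in (+1.0, -1.0):
        rot2d = rotation_about_axis(np.array([0.0, 0.0, 1.0]),
                                    s * np.radians(55.0))
        tgt_cnext = _NGLY_STD + 1.37 * (rot2d @ g)
        if best is None or np.linalg.norm(tgt_cnext) < np.linalg.norm(best):
            best = tgt_cnext
    src = np.array([pos["C1'"], pos[ngly], pos[cnext]])
    tgt = np.array([_C1P_STD, _NGLY_STD, best])
    r, t = kabsch(src, tgt)
    out = {n: apply_rigid(p, r, t) for n, p in pos.items()}
    if mirror:
        flip = rotation_about_axis(np.array([1.0, 0.0, 0.0]), np.pi)
        out = {n: flip @ p for n, p in out.items()}
    return out


_PHOSPHATE = ("P", "OP1", "OP2")
_O5_O3_GAP = 2.52   # |O5'(i) - O3'(i-1)| for P-O 1.6 A and O-P-O 104 deg


def _sugar_atoms(res_name: str) -> list[str]:
    """Sugar atoms (no phosphate): rotate rigidly about the glycosidic bond."""
    tpl = get_template(res_name)
    return [n for n in tpl.atom_names if "'" in n]


def _reconnect_backbones(placed: list[list[dict]], names: list[list[str]],
                         orders: list[list[int]], n_sweeps: int = 4) -> None:
    """Choose each nucleotide's glycosidic torsion so the sugar-phosphate
    backbone reconnects, then place the bridging phosphates analytically.

    Bases stay fixed (they define the pairing); sugars swing about the
    glycosidic bond to bring each O5' within bridging distance of the
    previous residue's O3', avoiding steric overlap; each internal P is
    finally set equidistant (1.6 A) from the two oxygens it bridges.
    ``placed`` is mutated in place; ``orders`` lists, per strand, the pair
    indices in that strand's 5'->3' chain order.
    """
    n_str = len(placed)

    def context(s, i):
        ctx = []
        for s2 in range(n_str):
            for i2 in range(len(placed[s2])):
                if (s2, i2) == (s, i):
                    continue
                ctx.extend(p for n2, p in placed[s2][i2].items()
                           if n2 not in _PHOSPHATE)
        return np.asarray(ctx)

    for sweep in range(n_sweeps):
        for s, order in enumerate(orders):
            for k, i in enumerate(order):
                res_name = names[s][i]
                pos = placed[s][i]
                sugar = _sugar_atoms(res_name)
                axis_a = pos[_GLY_N[res_name]]
                axis = pos["C1'"] - axis_a
                prev_o3 = placed[s][order[k - 1]]["O3'"] if k > 0 else None
                next_o5 = (placed[s][order[k + 1]]["O5'"]
                           if k + 1 < len(order) else None)
                ctx = context(s, i)
                moving0 = np.array([pos[n] for n in sugar])
                io5 = sugar.index("O5'")
                io3 = sugar.index("O3'")
                best, best_score = None, None
                for chi_deg in range(0, 360, 5):
                    rot = rotation_about_axis(axis, np.radians(chi_deg))
                    moving = axis_a + (moving0 - axis_a) @ rot.T
                    score = 0.0
                    if prev_o3 is not None:
                        score += abs(np.linalg.norm(moving[io5] - prev_o3)
                                     - _O5_O3_GAP)
                    if next_o5 is not None:
                        score += abs(np.linalg.norm(moving[io3] - next_o5)
                                     - _O5_O3_GAP)
                    dmin = np.sqrt(((moving[:, None, :] - ctx[None, :, :]) ** 2
                                    ).sum(-1)).min(axis=1)
                    score += float(np.clip(2.6 - dmin, 0.0, None).sum()) * 2.0
                    if best_score is None or score < best_score - 1e-9:
                        best, best_score = moving, score
                for n, p in zip(sugar, best):
                    pos[n] = p

    # place phosphates: internal ones bridge O5'(i) and O3'(i-1)
    for s, order in enumerate(orders):
        for k, i in enumerate(order):
            pos = placed[s][i]
            o5 = pos["O5'"]
            if k == 0:
                # 5' terminus: extend from the sugar with ideal geometry
                d = o5 - pos["C5'"]
                p = o5 + 1.6 * d / np.linalg.norm(d)
            else:
                o3 = placed[s][order[k - 1]]["O3'"]
                mid = 0.5 * (o5 + o3)
                ab = o3 - o5
                dist = np.linalg.norm(ab)
                h = np.sqrt(max(1.6 ** 2 - (dist / 2.0) ** 2, 0.0))
                if h > 0:
                    # pick the circle point with the most clearance from the
                    # two sugars it bridges (their O5'/O3' are its bond mates)
                    perp = np.cross(ab, np.array([0.0, 0.0, 1.0]))
                    if np.linalg.norm(perp) < 1e-8:
                        perp = np.cross(ab, np.array([1.0, 0.0, 0.0]))
                    perp /= np.linalg.norm(perp)
                    perp2 = np.cross(ab / dist, perp)
                    cands = [mid + h * (np.cos(t) * perp + np.sin(t) * perp2)
                             for t in np.linspace(0, 2 * np.pi, 24, endpoint=False)]
                    ctx = [q for n2, q in pos.items()
                           if n2 not in ("O5'", "P", "OP1", "OP2")]
                    ctx += [q for n2, q in placed[s][order[k - 1]].items()
                            if n2 != "O3'"]
                    ctx = np.asarray(ctx)
                    p = max(cands, key=lambda c: float(
                        np.linalg.norm(ctx - c, axis=1).min()))
                else:
                    p = mid
            pos["P"] = p
            # OP1/OP2 complete a near-tetrahedral phosphate
            u1 = pos["O5'"] - p
            u1 /= np.linalg.norm(u1)
            if k > 0:
                u2 = placed[s][order[k - 1]]["O3'"] - p
                u2 /= np.linalg.norm(u2)
            else:
                u2 = np.cross(u1, np.array([0.0, 0.0, 1.0]))
                u2 /= np.linalg.norm(u2)
            b = -(u1 + u2)
            b /= np.linalg.norm(b)
            perp = np.cross(u1, u2)
            perp /= np.linalg.norm(perp)
            half = np.radians(59.8)
            pos["OP1"] = p + 1.48 * (np.cos(half) * b + np.sin(half) * perp)
            pos["OP2"] = p + 1.48 * (np.cos(half) * b - np.sin(half) * perp)


def build_bdna(sequence: str, chain_ids: tuple[str, str] = ("B", "C"),
               start_number: int = 1) -> ComplexStructure:
    """Idealized B-DNA duplex for ``sequence`` (given 5'->3' for strand 1).

    Strand 2 is the reverse complement, antiparallel.  Consecutive pairs are
    related by a 3.38 A rise and 36 deg twist about the z axis.
    """
    sequence = sequence.upper()
    if any(b not in "ACGT" for b in sequence):
        raise ValueError(f"invalid base in {sequence!r}")
    n = len(sequence)
    z = np.array([0.0, 0.0, 1.0])

    placed1, placed2 = [], []
    for i, b in enumerate(sequence):
        rot = rotation_about_axis(z, np.radians(TWIST * i))
        shift = np.array([0.0, 0.0, RISE * i])
        p1 = _place_base("D" + b, mirror=False)
        p2 = _place_base("D" + DNA_COMPLEMENT[b], mirror=True)
        placed1.append({k: rot @ v + shift for k, v in p1.items()})
        placed2.append({k: rot @ v + shift for k, v in p2.items()})

    # reconnect backbones: strand 1 runs 5'->3' with i, strand 2 opposite
    comp = [DNA_COMPLEMENT[b] for b in sequence]
    _reconnect_backbones(
        [placed1, placed2],
        [["D" + b for b in sequence], ["D" + b for b in comp]],
        [list(range(n)), list(range(n - 1, -1, -1))],
    )

    c1, c2 = chain_ids
    chains = {c1: [], c2: []}
    for i, b in enumerate(sequence):
        chains[c1].append(_residue_from_template(
            "D" + b, placed1[i], c1, start_number + i))
    for j in range(n):
        i = n - 1 - j
        chains[c2].append(_residue_from_template(
            "D" + comp[i], placed2[i], c2, start_number + j))
    return ComplexStructure(chains, provenance="synthetic B-DNA")


# --------------------------------------------------------------------------
# extended peptide
# --------------------------------------------------------------------------

_BB_GEOM = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
            "N-CA-C": 111.0, "CA-C-N": 116.7, "C-N-CA": 121.5,
            "CA-C-O": 120.4}


def build_peptide(sequence: str, chain_id: str = "A",
                  phi: float = -120.0, psi: float = 120.0,
                  start_number: int = 1) -> ComplexStructure:
    """Extended peptide (single chain) with ideal template side chains."""
    if any(a not in ONE_TO_THREE for a in sequence):
        raise ValueError(f"invalid amino acid in {sequence!r}")
    rad = np.radians
    bb = []   # per residue dict N/CA/C/O
    for i, aa in enumerate(sequence):
        if i == 0:
            n = np.zeros(3)
            ca = n + np.array([_BB_GEOM["N-CA"], 0.0, 0.0])
            d = rotation_about_axis(np.array([0, 0, 1.0]),
                                    np.pi - rad(_BB_GEOM["N-CA-C"]))
            c = ca + _BB_GEOM["CA-C"] * (d @ np.array([1.0, 0, 0]))
        else:
            prev = bb[-1]
            n = place_atom(prev["N"], prev["CA"], prev["C"],
                           _BB_GEOM["C-N"], rad(_BB_GEOM["CA-C-N"]), rad(psi))
            ca = place_atom(prev["CA"], prev["C"], n,
                            _BB_GEOM["N-CA"], rad(_BB_GEOM["C-N-CA"]),
                            np.pi)          # omega = 180
            c = place_atom(prev["C"], n, ca,
                           _BB_GEOM["CA-C"], rad(_BB_GEOM["N-CA-C"]), rad(phi))
        bb.append({"N": n, "CA": ca, "C": c})
    # carbonyl O: trans to the next N (or psi+180 for the C terminus)
    for i in range(len(sequence)):
        nxt = bb[i + 1]["N"] if i + 1 < len(sequence) else None
        if nxt is not None:
            d = bb[i]["C"] - (bb[i]["CA"] + nxt) / 2.0
        else:
            d = place_atom(bb[i]["N"], bb[i]["CA"], bb[i]["C"],
                           1.0, rad(_BB_GEOM["CA-C-O"]), rad(psi + 180.0)) \
                - bb[i]["C"]
        bb[i]["O"] = bb[i]["C"] + _BB_GEOM["C-O"] * d / np.linalg.norm(d)

    residues = []
    for i, aa in enumerate(sequence):
        res_name = ONE_TO_THREE[aa]
        tpl = get_template(res_name)
        src = np.array([tpl.positions[x] for x in ("N", "CA", "C")])
        tgt = np.array([bb[i][x] for x in ("N", "CA", "C")])
        r, t = kabsch(src, tgt)
        coords = {x: bb[i][x] for x in ("N", "CA", "C", "O")}
        for name in tpl.atom_names:
            if name not in coords:
                coords[name] = apply_rigid(tpl.positions[name], r, t)
        residues.append(_residue_from_template(
            res_name, coords, chain_id, start_number + i))
    return ComplexStructure({chain_id: residues}, provenance="synthetic peptide")


# --------------------------------------------------------------------------
# docked toy complex
# --------------------------------------------------------------------------

def build_toy_complex(spec: FixtureSpec = FixtureSpec(),
                      protonate: bool = True) -> ComplexStructure:
    """Peptide docked against an idealized duplex, interface area > 100 A^2.

    The peptide approaches along +x (roughly the major-groove face of the
    pair frame), its axis parallel to the helix axis; the closest approach
    with all cross-partner heavy-atom distances >= 2.7 A is used, plus any
    requested extra offset.  Deterministic given the spec.
    """
    dna = build_bdna(spec.dna_sequence)
    pep = build_peptide(spec.peptide_sequence)

    # orient peptide long axis along z, centered against the duplex mid-height
    pcoords = pep.coords()
    centroid = pcoords.mean(axis=0)
    # principal axis
    u, s, vt = np.linalg.svd(pcoords - centroid)
    axis = vt[0]
    rot, _ = kabsch(np.array([centroid, centroid + axis, centroid + vt[1]]),
                    np.array([[0.0, 0.0, 0.0], [0, 0, 1.0], [0, 1.0, 0]]))
    mid_z = 0.5 * RISE * (len(spec.dna_sequence) - 1)
    dna_xy = dna.coords()[:, :2]

    def placed(dist):
        t = np.array([dist, 0.0, mid_z]) - rot @ centroid
        return pep.transformed(rot, t)

    dcoords = dna.coords()
    best = None
    for dist in np.arange(30.0, 2.0, -0.25):
        trial = placed(dist)
        tc = trial.coords()
        dmin = np.sqrt(
            ((tc[:, None, :] - dcoords[None, :, :]) ** 2).sum(-1)).min()
        if dmin < 2.7:
            break
        best = dist
    if best is None:
        raise StructureError("docking failed: peptide always clashes")
    final = placed(best + spec.docking_offset)

    chains = dict(final.chains)
    chains.update(dna.chains)
    out = ComplexStructure(chains, provenance=f"synthetic complex {spec.seed}")
    if spec.perturbation > 0:
        rng = np.random.default_rng(spec.seed)
        for a in out.atoms():
            a.position = a.position + rng.normal(0.0, spec.perturbation, 3)
    out = assign_partners(out, tuple(final.chains), tuple(dna.chains))
    if protonate:
        out = add_hydrogens(out)
    return out


# --------------------------------------------------------------------------
# synthetic feature / ddG tables
# --------------------------------------------------------------------------

from .energetics import FEATURE_NAMES  # noqa: E402  (canonical feature order)

# documented default linear model for synthetic tables: plausible signs and
# scales for each feature (destabilizing mutations lose favourable terms)
DEFAULT_COEFFICIENTS = {
    "sa_ratio_com_p2": 0.15, "ddg_solv": 0.04, "d_nhbond_p1p2": -0.25,
    "elec_mut_p1p2": -0.01, "nhbond_wt_site_all": 0.30, "l_mut": -0.002,
    "dd_evdw_site_all": 0.12, "d_e_fold": 0.35, "location_mut": 0.60,
}
DEFAULT_INTERCEPT = 0.25


def generate_feature_dataset(n: int = 219, true_coefficients: dict | None = None,
                             intercept: float = DEFAULT_INTERCEPT,
                             noise_sd: float = 0.86, n_complexes: int = 49,
                             seed: int = 0):
    """Synthetic mutation table with known affine ddG structure.

    Features are drawn from simple distributions on the scales the real
    structural features take; ``ddg_exp`` is the affine model plus Gaussian
    noise.  Complex ids are assigned in contiguous blocks so that
    leave-one-complex-out splitting is meaningful.  Returns a pandas
    DataFrame in the layout of :class:`dnabind.model.MutationDataset`.
    """
    import pandas as pd
    if n < 20:
        raise ValueError("n must be >= 20")
    if n_complexes < 2:
        raise ValueError("n_complexes must be >= 2")
    if n_complexes > n:
        raise ValueError("n_complexes cannot exceed n")
    coeffs = dict(DEFAULT_COEFFICIENTS)
    if true_coefficients:
        coeffs.update(true_coefficients)
    rng = np.random.default_rng(seed)
    feats = {
        "sa_ratio_com_p2": 1.0 + rng.lognormal(0.5, 0.5, n),
        "ddg_solv": rng.normal(0.0, 4.0, n),
        "d_nhbond_p1p2": rng.integers(-3, 3, n).astype(float),
        "elec_mut_p1p2": rng.normal(-30.0, 20.0, n),
        "nhbond_wt_site_all": rng.poisson(1.5, n).astype(float),
        "l_mut": rng.integers(40, 300, n).astype(float),
        "dd_evdw_site_all": rng.normal(0.0, 2.5, n),
        "d_e_fold": rng.normal(0.0, 1.2, n),
        "location_mut": rng.integers(0, 2, n).astype(float),
    }
    y = intercept + sum(coeffs[k] * feats[k] for k in FEATURE_NAMES)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n)
    complex_ids = np.sort(rng.integers(0, n_complexes, n - n_complexes))
    complex_ids = np.concatenate([np.arange(n_complexes), complex_ids])
    complex_ids = np.sort(complex_ids)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    wt = rng.choice(aas, n)
    mut = rng.choice(aas, n)
    df = pd.DataFrame({
        "complex_id": [f"cmplx{c:03d}" for c in complex_ids],
        "chain": "A",
        "wt": wt, "pos": rng.integers(1, 200, n), "mut": mut,
        "ddg_exp": y,
    })
    for k in FEATURE_NAMES:
        df[k] = feats[k]
    return df
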