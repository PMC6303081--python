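# Methods

This note documents the models, numerical choices and limitations behind
`dnabind`. It is the package's own account: every number quoted here is
recomputed by the test suite or by `scripts/acceptance.py`.

## The prediction pipeline

Given a protein–DNA complex (partner 1 = protein chains, partner 2 = DNA
chains) and one substitution, the pipeline is:

1. **Input gates.** The file must contain at least two chains; the first
   model of an NMR ensemble is used; alternate locations resolve to the
   highest-occupancy conformer (ties to the first listed); non-standard
   residues are dropped with a warning. The two partners must bury more
   than 100 Å² of solvent-accessible surface, computed as
   SASA(p1) + SASA(p2) − SASA(complex) with unbound partners taken rigidly
   from the complex coordinates. Up to 16 mutations per run, each treated
   independently.
2. **Preparation.** Missing heavy side-chain atoms are rebuilt from ideal
   residue templates; hydrogens are added geometrically (below).
3. **Mutant build.** The mutated residue keeps its backbone; the new side
   chain is posed from the ideal template and sampled over a coarse
   backbone-independent rotamer library (χ ∈ {−60°, 60°, 180°} per rotatable
   bond, prior weights 0.35/0.20/0.45 favouring trans and gauche⁻). The
   rotamer minimizing a repulsive-only Lennard-Jones clash score against all
   heavy atoms within 10 Å wins; ties break to the higher prior weight, then
   the lower index, making the build bit-for-bit deterministic. Neighbouring
   side chains are not repacked — the subsequent minimization absorbs the
   residual strain.
4. **Minimization.** Both wild-type and mutant complexes are minimized for
   100 conjugate-gradient steps in the gas phase with harmonic restraints
   (5 kcal mol⁻¹ Å⁻²) on the backbone atoms of all residues — protein
   N/CA/C/O and the DNA sugar-phosphate backbone, an interpretation we make
   explicit because "backbone atoms of all residues" could be read as
   protein-only. Unbound partner coordinates are afterwards extracted
   rigidly from the minimized complex (rigid-body binding assumption).
5. **Features and score.** Nine features (below) feed an ordinary least
   squares regression; predicted ΔΔG ≥ 1.10 kcal/mol ⇒ deleterious.

## Force field

A compact CHARMM-shaped potential: harmonic bonds and angles, 6-12
Lennard-Jones with R_min,ij = rmin_half_i + rmin_half_j and
ε_ij = √(ε_i ε_j), Coulomb with k_C = 332.0636 kcal·Å/(mol·e²) and ε = 1,
12 Å cutoff, 1-2/1-3 exclusions. Parameters ship as a plain-text table
(`data/ff_params.tsv`, one row per residue/atom: charge, R_min/2, ε, PB
radius). Charges are assigned by chemically motivated group rules (amide,
hydroxyl, carboxylate, guanidinium, phosphate, nucleobase rings) and each
residue's total is snapped exactly to its canonical integer charge at
neutral pH (Arg/Lys +1, Asp/Glu −1, His neutral Nδ1-H tautomer, −1 per
nucleotide) — for amino acids via a nonpolar buffer carbon, for nucleotides
spread evenly over the five sugar carbons so no atom ends up implausibly
charged. The values are internally consistent rather than a copy of any
published force field: they feed a regression that is retrained on data
produced with them, so consistency matters more than parity.

Bond and angle equilibria are measured from the ideal residue geometry of
the Chemical Component Dictionary bundled with biotite at topology-build
time; inter-residue links (peptide C–N 1.329 Å, phosphodiester O3'–P
1.607 Å and their flanking angles) are small hard-coded constants. Force
constants are generic (300 kcal mol⁻¹ Å⁻² heavy–heavy bonds, 350 for X–H,
50 kcal mol⁻¹ rad⁻² angles); hydrogen-containing bonds are kept stiff
rather than constrained, which is equivalent under gradient descent.

**Minimizer.** Polak–Ribière conjugate gradient with backtracking line
search, per-atom step cap 0.25 Å, early stop below an RMS gradient of
0.05 kcal mol⁻¹ Å⁻¹. Hard clashes from freshly built rotamers are
pre-relieved by a few capped steepest-descent moves. Reported energies use
plain truncation at the cutoff; the minimizer's own objective shifts each
nonbonded term to vanish at the cutoff (gradients inside the cutoff are
unchanged). Plain truncation is discontinuous when a pair crosses 12 Å and
a line search can wedge against that jump; the shifted objective is the
standard cure and guarantees the monotone non-increasing energy trace.

## Hydrogen placement

Each template hydrogen stores internal coordinates (bond, angle, dihedral)
relative to three reference atoms chosen within its rigid local group, and
is replayed onto actual coordinates by NeRF construction. The backbone
amide H is special-cased into the peptide plane, trans to the preceding
carbonyl. N-termini carry a single amide H (not NH₃⁺) and 5'-terminal
nucleotides keep their phosphate; acid protons and leaving atoms of the
free monomers are removed. Placement is idempotent and never moves heavy
atoms.

## Polar solvation (Poisson solver)

The reaction-field energy is computed on a cubic grid with a 7-point
finite-difference stencil, face-centred dielectric (ε_in = 2 inside the
union of atom PB spheres, ε_out = 80 outside; molecular surface without
reentrant refinement), trilinear charge spreading and Dirichlet boundaries
from the ε_out-screened Coulomb potential. Zero ionic strength reduces the
linearized Poisson–Boltzmann equation to pure Poisson; the linear system is
solved by Jacobi-preconditioned conjugate gradients (rtol 10⁻⁷). A coarse
solve (0.9 Å spacing, 16 Å margin) supplies focused boundary conditions to
a finer grid (0.6 Å, 8 Å padding). The grid self-energy of spread charges
is removed by a reference solve with uniform ε_in on the identical grid;
E = ½ Σ qᵢφ(rᵢ) differences between the two solves are then self-energy
free, which is what makes ΔG_solv = G_com − G_p1 − G_p2 and its
wild-type/mutant difference grid-stable.

Accuracy at the shipped spacings: a Born ion (q = 1 e, R = 2 Å,
ε 1→80) reproduces the closed form within ~4 % and a Kirkwood dipole in a
3 Å sphere within ~3 %; on the toy complex ΔG_solv changes by <1 % between
0.6 Å and 0.35 Å grids. We chose 0.9/0.6 Å as the default because the
finer grid costs ~6× more while the quantity entering the regression is a
difference that is already grid-stable; pass finer spacings through
`PBSettings` where absolute accuracy matters.

## The nine features

| feature | meaning |
| --- | --- |
| `ddg_solv` | ΔG_solv(mutant) − ΔG_solv(wild), each G_com − G_p1 − G_p2 |
| `dd_evdw_site_all` | LJ energy of site vs all atoms within 10 Å, mut − wt |
| `elec_mut_p1p2` | Coulomb (ε = 1) between partners within 10 Å, mutant |
| `d_nhbond_p1p2` | protein–DNA H-bond count, mut − wt |
| `nhbond_wt_site_all` | H-bonds between the wild-type site and the rest |
| `sa_ratio_com_p2` | SASA(complex)/SASA(DNA), wild type |
| `location_mut` | 1 iff site SASA in complex < in unbound partner |
| `d_e_fold` | Σ contacts M(mut, aa_j) − M(wt, aa_j), Cβ–Cβ ≤ 6.5 Å |
| `l_mut` | length of the mutated chain (residues) |

Details and choices: "within 10 Å" is measured atom-to-atom and a pair
qualifies when its own distance is ≤ 10 Å; the site's 1-2/1-3 covalent
neighbours across the peptide link are excluded from the vdW sum. Hydrogen
bonds are donor–H…acceptor triples with H…A ≤ 2.5 Å and ∠D–H–A ≥ 90°
(inclusive limits), both directions between the two selections;
donor/acceptor chemistry is derived from the covalent topology (donor:
N/O/S with a bound H; acceptor: any O, or an N with no hydrogen and at most
two heavy neighbours) rather than a shipped table. Intra-residue triples
and acceptors bonded to the donor never count. SASA is Shrake–Rupley with
960 Fibonacci-lattice points per atom, probe 1.4 Å, element radii, heavy
atoms only; the interface test uses strict inequality with a 10⁻³ Å²
tolerance (ties ⇒ not interface). The contact-potential matrix shipped in
`data/synthetic_contact_potential.txt` is a synthetic stand-in (symmetric
20×20 from hydrophobicity products) because the published AAindex matrix it
replaces cannot be redistributed here; the Cβ 6.5 Å contact-sum that turns
a pairwise matrix into a per-mutation scalar is likewise this package's
documented choice. Since the regression is retrained on features produced
by these definitions, internal consistency is the operative requirement.

## Regression, cross-validation, classification

Ordinary least squares of experimental ΔΔG on the nine features
(statsmodels), with two-sided t-test p-values and standardized coefficients
(β·sd(x)/sd(y)) as importances; rank-deficient designs are rejected naming
the constant/collinear columns. Cross-validation: CV1 = random 50/50
mutation split × 50 repeats, CV2 = 80/20 × 50, CV3 = leave-one-complex-out;
sampling is without replacement, unstratified, from a seeded generator, and
metrics are computed on pooled out-of-fold predictions (per-fold R/RMSE and
per-fold coefficient means/SDs are also reported). Classification labels
are experimental ΔΔG ≥ 1 kcal/mol; ROC/PR curves come from scikit-learn,
AUCs by trapezoid, MCC from its defining formula at the operating
threshold, which defaults to the ER-minimizing prediction threshold
(ties → the larger, more specific threshold). Variance inflation factors
are 1/(1−R_j²) with an intercept in each auxiliary regression.

## Synthetic fixtures: what they are and are not

`build_bdna` places base pairs on standard-frame anchors with a 3.38 Å rise
and 36° twist, Watson–Crick complement antiparallel; sugars swing about the
glycosidic bond to reconnect the backbone and bridging phosphates are
placed analytically between consecutive O5'/O3' oxygens. The result is a
recognizably B-form duplex — the idealized geometry shows 20 inter-strand
hydrogen bonds on an 8-mer and connects every backbone link to ≤ 2.2 Å —
but it is not crystal-quality: sugar puckers are inherited from the ideal
monomer and sequence-dependent deformation is absent. The peptide is built
extended (φ/ψ = −120°/120°) and docked along +x until contact, which
passes the 100 Å² gate (~240 Å² for the default 5-mer) yet buries far less
surface than a real protein–DNA interface. Consequently, passing tests on
these fixtures validates the machinery — geometry, energies, counts,
determinism, the regression — not predictive accuracy on real complexes;
the feature↔ΔΔG relationship in the synthetic tables is linear by
construction with noise SD 0.86 kcal/mol, n = 219 over 49 complexes,
mirroring the scale of curated experimental sets for this problem.

The shipped default model (`data/default_model.json`) is trained on that
synthetic reference table (seed 2018) because the original method's fitted
weights are not published. Its predictions demonstrate the pipeline;
retrain on experimental data for scientific use.

## Degenerate inputs and tie-breaks

Self-mutations return an identical structure object and, because every
stage is deterministic, all difference features are exactly 0.0 through the
full pipeline. Empty structures, single-chain files, unknown residues or
atoms, mismatched wild-type identities, >16 mutations, single-class label
vectors and single-complex CV3 all fail fast with specific messages.
Rotamer ties, ER-threshold ties and altloc ties have fixed documented
resolutions, so identical inputs and seeds reproduce identical bytes.

## Known limitations

- No switching function on reported truncated sums; absolute nonbonded
  energies near the cutoff carry O(q²/r_c) truncation terms.
- Shrake–Rupley areas are orientation-dependent at the ~0.3 % level with
  960 points/atom; translation leaves them bit-identical, rotation does
  not (tests budget 0.5 % for rotational invariance).
- The Poisson dielectric boundary is the union of atom spheres; no probe
  reentrant surface, so absolute solvation energies run slightly deep.
- Rigid unbound partners, fixed backbone at the site, no neighbour
  repacking, single N-terminal amide H, no crystallographic symmetry
  expansion, no mmCIF, no RNA partners, zero ionic strength only.
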