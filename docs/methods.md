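# Methods

This note documents the models, parameter choices and numerical conventions
behind `pocketconf`, and what the synthetic test fixtures do and do not
establish about real protein–ligand systems.

## Active-site definition

The pocket is selected at residue granularity: a residue is kept whole or
not at all.  Two readings of "residues within R of the ligand" are
implemented because they differ materially for an elongated ligand:

- `com_sphere`: keep a residue if any of its atoms lies within R of the
  ligand's centre of mass;
- `any_atom` (default): keep a residue if its minimum atom-to-ligand-atom
  distance is within R.

Default R = 6.0 Å.  The centre-of-mass sphere is geometrically much smaller
than the any-atom criterion for the same R; for an extended secosteroid the
literal centre-of-mass reading selects far fewer atoms, so the any-atom mode
is the default and both are exposed.  Waters are parsed but excluded from
selection by default; they can be included with a flag.

Protonation is template-based for pH ≈ 7.4: aspartate/glutamate carboxylates
bare, lysine ammonium and arginine guanidinium fully protonated, histidine
neutral in the N-epsilon tautomer, hydroxyl/thiol/amide groups with their
neutral hydrogen complement, and one amide hydrogen per backbone nitrogen
(none for proline).  Hydrogens are placed at standard bond lengths (N–H
1.01 Å, O–H 0.96 Å, S–H 1.34 Å) completing roughly tetrahedral local
geometry; existing hydrogens are counted first, so the operation is
idempotent.  This is a *polar-hydrogen* model: nonpolar C–H hydrogens are
not generated, since neither the clash filter nor the nonbonded surrogate
downstream requires them.  No pKa calculation is attempted — only the
standard physiological states matter downstream.

Cut peptide bonds are capped with hydrogens: 1.01 Å along the former N→C
direction at an exposed backbone nitrogen, 1.09 Å along the former C→N
direction at an exposed carbonyl carbon.  When the parent structure is
available the true positions of the absent partners orient the caps, and a
partner absent from the parent as well is treated as a genuine chain
terminus (no cap); without a parent, local backbone geometry (CA, O)
supplies the direction.

## Conformer generation

Dihedral scanning uses the input pose as the 0° reference of every scanned
torsion; scan values are offsets applied by right-hand-rule rotation about
the j→k bond axis (the measurement convention is chosen so a rotation by +θ
increases the measured torsion by θ).  Poses are the full Cartesian product
of dihedral increments and a rigid translation grid (default 3×3×3 points,
±1.0 Å per axis), enumerated in deterministic lexicographic order with a
configurable cap (default 2×10⁶) against combinatorial blow-ups.

Sterically infeasible poses are removed when any ligand–site distance falls
below 0.7 × (sum of van der Waals radii).  Survivors are relaxed with
L-BFGS-B over the free atoms (default: ligand plus site hydrogens; site
heavy atoms never move), converging when the largest gradient component
drops below 10⁻⁴ kcal/mol/Å or after 2000 steps.  Because a relaxed pose
may migrate out of the basin of its generating grid point, conformers are
characterised after minimization by their *measured* dihedrals; the
generating grid tuple is retained as provenance.

Deduplication clusters greedily in ascending-energy order: a pose is
distinct if its best-superposition (Kabsch, proper rotation enforced) RMSD
to every kept pose exceeds 0.5 Å.  Minimum verification builds a
central-difference Hessian (step 10⁻³ Å) over the free coordinates and
requires no eigenvalue below −10⁻⁶ (absorbing near-zero rigid-body modes);
it refuses non-stationary inputs rather than misreport them.

## Energetics

The surrogate backend is a Dreiding-flavoured *nonbonded* force field:
12-6 Lennard-Jones with Lorentz–Berthelot combination (packaged R₀/D₀ per
element for H, C, N, O, F, P, S, Cl), an optional 12-10 hydrogen-bond well
E = D_hb[5(R_hb/r)¹² − 6(R_hb/r)¹⁰] substituted for the Lennard-Jones term
of geometrically detected D–H···A pairs (D_hb = 4.0 kcal/mol, R_hb =
2.75 Å), and Coulomb electrostatics with k = 332.0637 kcal·Å/(mol·e²) under
a constant or distance-dependent dielectric.  1-2 and 1-3 pairs are
excluded when a bond list is supplied.  Valence terms are intentionally
absent — fragments are internally rigid or relaxed by the backend — but the
backend accepts harmonic pair restraints (used by the toy ligand to hold
bond lengths and 1-3 distances, leaving torsions free).  Gradients are
analytic and are checked against central differences in the test suite.

The two-layer extrapolation, population analysis and binding decomposition
are exact arithmetic on backend energies; populations use the max-shifted
softmax with a deterministic summation order, so they are overflow-safe and
invariant to adding a constant to all energies.  Temperature defaults to
298.15 K everywhere, including the dissociation-constant bridge
ΔG = RT ln(K_d / 1 M).

## NCI analysis

The promolecular density is a sum of spherical atomic densities, each a sum
of pure exponential shells ρ_atom(r) = Σ c_i exp(−r/ζ_i) (atomic units).
Shell parameters for H–Ar are generated from Slater screening rules: a
shell with principal number n and screened charge Z_eff decays with length
ζ = n/(2 Z_eff) bohr and its coefficient normalises the shell to its
electron count, c = n_e/(8π ζ³).  This keeps every atomic density positive,
strictly decreasing and analytically differentiable — gradient and Hessian
are closed-form, never finite-differenced.  The parameterization is a
deliberately simple in-house model: absolute densities are approximate, but
every quantity the package derives from them (RDG, sign(λ₂)ρ, the
classification bands) is checked against closed forms that hold for any
exponential-shell model.

Grids are axis-aligned with 0.2 bohr default spacing and 2.0 Å padding
(the pipeline default coarsens this to 0.5 bohr for speed).  Points with
ρ > 0.05 a.u. are masked out of the 2D scatter as covalent/core regions;
with `intermolecular_only`, a point must draw at least a 5% density share
from the ligand and from the environment alike.  The vdW classification
band is |sign(λ₂)ρ| ≤ 0.01 a.u.  Cube files carry the conventional RDG
isovalue 0.3 a.u. in their metadata.  Hessian eigenvalues come from the
symmetric eigensolver with ascending ordering, so λ₂ is always the middle
eigenvalue.

Hydrogen bonds are detected geometrically: donor = O/N/S covalently bonded
to the hydrogen (covalent-radius cutoff + 0.4 Å), acceptor = O/N/S with
H···A ≤ 2.5 Å and D–H···A ≥ 120°; the donor's fragment tag assigns the
ligand→protein / protein→ligand role.  No energetic ranking is implied by
the ordering (contacts sort by distance).

## Spectra

Broadening is performed in the wavelength domain with peak amplitudes
proportional to oscillator strength — the quantities of interest here are
normalized band shapes, maxima and shifts, for which the molar-absorptivity
prefactor cancels.  The default grid is 120–400 nm at 0.1 nm and the
default width 20 nm FWHM.  λ_max ties resolve to the longest wavelength.
The predominant transition of a table is the flagged row if present,
otherwise the largest-f row.  LE/ICT/ECT character labels are carried as
annotations only; assigning them requires orbital densities outside this
package's scope.

## The synthetic generator

`make_toy_complex` builds a carbon-chain ligand (bond 1.5 Å, tetrahedral
zigzag) inside a pocket engineered so that the scan-grid global minimum —
and the continuous minimum reachable by relaxation — sits at a prescribed
("planted") dihedral tuple with the identity translation:

- chain atoms carry alternating-sign partial charges with magnitudes graded
  along the chain (±0.35 e × (1 + 0.15 i)), which localises each atom to
  its own wells and breaks the head–tail symmetry of the chain;
- each atom gets a pair of oppositely charged oxygen "attractors" placed at
  the optimum distance of the combined LJ + Coulomb pair potential from the
  atom's planted position, fanned ±40° about the chain axis.  A single well
  is a sphere, and a torsion circle meets a sphere at two mirror-related
  points; the split pair is satisfied simultaneously only at the planted
  geometry, which removes the reflection degeneracy that would otherwise
  produce a near-degenerate mirror conformer;
- a seeded cage of nitrogen atoms (ε = 10⁻⁴ kcal/mol) on a 7 Å sphere adds
  pocket scenery without moving the optimum.

The generator is a pure function of its spec and seed.  Planted-minimum
recovery through the full scan → clash filter → minimize → deduplicate
chain is exact over all tested seeds.  What the toy establishes is that the
machinery finds an engineered global minimum reliably; it does not emulate
protein topology, chemically valid valences, solvation, or the rugged
near-degenerate landscapes of real pockets, so passing recovery tests says
nothing about sampling adequacy for a real ligand.

`make_energy_set` produces energy lists with prescribed consecutive gaps
(plus optional seeded jitter), and `energies_for_populations` inverts the
Boltzmann relation exactly, which is how population-structure fixtures with
known ground truth are built.  `make_hbond_dimer` places an O–H···O dimer
at an exact requested H···A distance and D–H···A angle.
`make_transition_table` draws seeded λ/f/μ_tr sticks with one designated
predominant state.

## Pipeline and reproducibility

Stages communicate through files (PDB/XYZ/TSV/cube) so each is re-runnable
in isolation.  The driver records a manifest with the configuration,
per-stage counts, the top conformer, and SHA-256 checksums of every output;
re-running the same configuration reproduces all numeric outputs
bit-for-bit (the manifest differs only in its timestamp fields).  The
pipeline's default problem size — 2 rotatable bonds × 90° steps × 27
translations = 432 poses, NCI at 0.5 bohr spacing — was chosen so a full
run completes in well under a minute on one CPU while still exercising
every stage.

## Known limitations

- The force field is a surrogate: its binding energies are internally
  consistent but not comparable to quantum-chemical or calibrated
  force-field values.
- Promolecular densities use the in-house Slater-shell parameterization,
  not a published fit; quantitative NCI values (e.g. exact signed-density
  minima) will differ from tools shipping fitted atomic densities, though
  classifications and invariances are model-independent.
- Protonation is rule-based and polar-only; histidine tautomer choice is
  fixed, and no pKa or hydrogen-bond-network optimization is performed.
- Ring-pucker sampling, receptor flexibility and link-atom (covalent
  boundary) two-layer schemes are out of scope; the ligand layer must be a
  complete molecule.
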