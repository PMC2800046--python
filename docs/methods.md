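# Methods

This note documents the models, numerical choices and limitations behind the
package, in the spirit of a methods supplement. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Structural model

A pose is an ordered map of chains → residues → atoms with explicit
Cartesian coordinates. The partition assigns each chain a role (light,
heavy, antigen); the antibody is the light+heavy pair. Two representations
exist:

* **full-atom** — all heavy atoms (hydrogens optional on input; all metric
  and scoring definitions use non-hydrogen atoms only);
* **centroid** — the four backbone atoms (N, Cα, C, O) plus one side-chain
  pseudo-atom placed at the geometric center of the side-chain heavy atoms
  (at Cα for glycine), used by the coarse low-resolution stage.

Switching back to full atoms grafts side chains from donor structures by
per-residue superposition of the N/Cα/C backbone triad, so a rigidly moved
backbone carries its side chains exactly; residues without a donor receive
idealized template side chains (linear heavy-atom chains with standard bond
geometry). Van der Waals radii are a fixed per-element table (C 1.7, N 1.55,
O 1.52, S 1.8, H 1.2 Å; pseudo-atom 2.0 Å).

PDB input drops waters and HETATM records, collapses altlocs to the
highest-occupancy conformer, preserves insertion codes in residue identity,
and flags residues missing backbone atoms so metric atom sets skip them.
Non-protein residues in antigen chains are excluded (they arrive as HETATM).

## Kinematics

Two fold trees govern how perturbations propagate:

* the **docking tree** — two flexible 6-DOF jumps, light↔heavy and
  antibody↔antigen. A jump move is a rotation + translation of the
  downstream body about its center of mass (the anchor choice is ours; the
  transform is an exact isometry of the body).
* the **loop tree** — per CDR a fixed jump across the stems (start−1 →
  stop+1) and a cutpoint at the loop middle (start + ⌊(stop−start)/2⌋).
  Torsions of residues up to the cut build forward from the start stem;
  residues after the cut build backward from the stop stem. Torsion changes
  are implemented as rigid rotations of the moving branch about the bond
  axis, so bond lengths and angles are never altered.

The **chainbreak deviation** at a cutpoint is the distance between the
actual amide nitrogen after the cut and its ideal position implied by
standard peptide geometry from the upstream residue (C–N 1.329 Å, Cα–C–N
116.2°, Engh–Huber-like constants; the ideal point is taken in the
Cα–C–N plane, which makes the measure zero exactly when bond length and
angle are ideal, independent of the free ψ dihedral, and invariant under
rigid motion).

**CCD closure** sweeps the loop's φ/ψ torsions. The moving anchors are a
virtual forward continuation of the chain across the cut (N, Cα, C of the
post-cut residue built from the upstream stem with ideal geometry; the two
continuation torsions are free closure DOFs); the fixed targets are the
actual backward-built N, Cα, C. Each update is the closed-form single-axis
minimizer of the squared anchor mismatch, so the objective is monotone
non-increasing per update. Defaults: tolerance 0.15 Å on the chainbreak
deviation, 100 sweeps maximum.

## Scoring

The score is a deliberately transparent analog of a coarse docking
potential, fully specified here (no external force-field dependence). Over
all non-hydrogen (or pseudo) atom pairs within 12 Å, excluding pairs within
one residue or between chain-adjacent residues:

* repulsion: `max(0, (r_ij − d)/r_ij)²` with `r_ij` the sum of vdW radii
  (weight 1.0);
* contact reward: `−exp(−(d − r_ij)² / 2σ²)`, σ = 1.5 Å (weight 0.5);
* electrostatics: Coulomb with distance-dependent dielectric ε = 4d over a
  small formal-charge table on terminal side-chain atoms (weight 0.25);
* chainbreak: `Σ deviation²` over the active cutpoints (weight 10.0);
* the cross-partner pair energies are carried as two separate terms —
  antibody–antigen and V_L–V_H — each with its own weight (both 1.0).

The **interface energy** used for ranking is exactly the weighted
antibody–antigen cross-partner term; it equals score(complex) −
score(partners rigidly separated) with internal DOFs frozen, and is zero
beyond the cutoff. The pair terms preserve the qualitative landscape the
protocol needs (clash relief, contact reward, closure pressure) but are not
a reconstruction of any published force field; absolute values are not
comparable to physical energies.

Minimization ("isolated-DOF") is derivative-free coordinate descent over
one DOF class at a time — one jump (3 translations + 3 rotations, initial
steps 0.2 Å / 2°) or one set of loop torsions (initial step 5°) — with
per-DOF step halving on failure, 50 iterations maximum and a 1e-4
improvement tolerance. Only improving steps are kept, so the score is
monotone non-increasing and frozen DOFs are bit-identical. Inside a
minimization the objective recomputes only pairs involving movable atoms
(plus a 6 Å neighbor-list margin beyond the 12 Å cutoff); the static-static
part is computed once.

Side-chain "packing" is a greedy one-sweep per-residue chi-grid search
(30° grid then 10° refinement, random residue order) on a local pair-energy
objective, with side chains treated as linear chi chains. This stands in
for rotamer-library packing; it never moves backbone atoms.

## The protocol

Defaults follow the printed protocol constants: 50 low-resolution cycles,
50 high-resolution Monte Carlo iterations, kT = 0.8, move weights
40/40/10/5/5 (antigen rigid body, V_L–V_H rigid body, all-CDR minimization,
H3 relax, H2 relax), local-start spin uniform 0–360° with tilt σ 8° and
translation σ 8 Å, slide-into-contact criterion 1 Å, 1000 decoys in local
mode and 5000 in global mode. Magnitudes the protocol inherits from prior
art without printing them are config-exposed with these defaults:
low-resolution antibody perturbation 0.7 Å / 5°, high-resolution rigid-body
perturbation 0.1 Å / 3° (both jumps), small/shear maximum angle 6°
(centroid) / 3° (full-atom), 5 small + 5 shear moves per loop relaxation.
The low-resolution H2+H3 relaxation runs once after the perturbation cycles
(a flag moves it inside the cycle); V_L–V_H is frozen during all loop
relaxation. After rigid-body moves the interfacial side chains are
repacked; after loop moves the loop and its ≤8 Å neighborhood (measured
between Cβ atoms, Cα for glycine). H2/H3 relaxations embed their own
minimization and receive no second one. The lowest-interface-energy
snapshot is tracked after every iteration and returned.

Decoy k of a batch uses seed `base_seed + k`, so batches are reproducible
and embarrassingly parallel; all samplers are pure functions of (state,
rng).

## The synthetic fixtures

`make_toy_complex` builds a three-chain poly-Ala/Gly complex with idealized
backbone geometry: helical framework segments interleaved with the six CDR
stretches on the light and heavy chains (a lysine per framework segment
gives packing something to do), the heavy chain placed at a ~4.5 Å closest
gap from the light chain, and a small helical antigen aimed at the H3
region, slid into contact, pressed to at least five cross-partner residue
contacts at the 5 Å criterion — and then **settled into the nearest
rigid-body local minimum of the package score**. The last step is what
makes the fixture behave like a native complex: a crystal structure sits in
a minimum of the true binding energy, so a fixture native that merely
grazes the surface would not anchor a docking funnel for any score. H3
defaults to 8 residues (inside the 7–11 range typical of benchmark sets);
total system size stays under 60 residues.

`make_homology_mimic` emulates homology-model error: each CDR's torsions
receive Gaussian noise and the loop is CCD-reclosed, with the noise
magnitude bisected (deterministically, fixed seed per loop) until the
loop's backbone rmsd to native lands within ±20% of the requested error
(default 2 Å); the V_L–V_H jump is then perturbed (default 3° / 0.5 Å).
`make_decoy_cloud` produces rigid antigen perturbations with known ligand
rmsd for testing metrics and funnel logic against ground truth.

What the fixtures do **not** emulate: real side-chain diversity and rotamer
statistics, β-sheet antibody topology, electrostatically polar interfaces,
buried waters, or realistic loop conformational preferences. Passing tests
demonstrate that the algorithmic machinery is correct and that the protocol
recovers a known binding mode on a controllable landscape — not that the
score function would rank real antibody–antigen decoys correctly.

## Evaluation

Ligand rmsd superposes the antibody backbone (N, Cα, C, O) by closed-form
least squares (determinant-corrected Kabsch) and measures the antigen
backbone deviation with no second superposition. Interface rmsd defines the
interface on the **native** complex (residues within 10 Å of a heavy atom of
the other partner), superposes the model over those backbone atoms and
measures the same atoms. f_nat counts native cross-partner residue contacts
(any heavy-atom pair ≤ 5 Å, defined on the native) recovered by the model.

The CAPRI table: incorrect if f_nat < 0.1 or (L > 10 and I > 4); high if
f_nat ≥ 0.5 and (L ≤ 1 or I ≤ 1); medium if (f_nat ≥ 0.3 and (L ≤ 5 or
I ≤ 2)) or (f_nat ≥ 0.5 and L > 1 and I > 1); acceptable otherwise. A
funnel exists when at least five of the ten lowest-interface-energy decoys
are medium **or better**; a `strict_medium` flag restores the literal
count-only-medium reading (a superset rating never demotes a decoy, so the
default is the more conservative convergence claim). Ranking ties break by
decoy index (stable sort).

Per-segment diversity statistics superpose the owning chain's framework and
query the CDR backbone (V_L–V_H: superpose light framework, query heavy
framework; paratope: superpose and query the paratope), reporting mean ± SD
over a decoy set.

## Problem sizes used in the shipped checks

The end-to-end docking-sanity batch runs 200 decoys at 20 low-resolution +
20 high-resolution cycles with a 5-iteration minimizer budget on the toy
fixture — a deliberate scale-down of the production defaults (50/50,
1000–5000 decoys) chosen so the whole suite stays desk-scale on one CPU;
the statistical checks (move frequencies, Metropolis rates) use 10⁵ draws.

## Known limitations

* The score is an analog, not a physical potential: absolute energies,
  funnel depths and the native's rank among exotic decoys are fixture-scale
  statements only.
* Side chains are linear chi chains; branched rotamers are approximated.
* Loop fragment insertion, backrub moves and flexibility outside the six
  CDRs are out of scope, as are explicit or implicit water models.
* Fold trees cover exactly the two topologies the protocol needs; there is
  no generic n-body tree or symmetry support.
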