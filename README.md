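# snugdock

Flexible-paratope Monte Carlo docking of antibody–antigen complexes.

Antibody homology models carry systematic errors exactly where binding
happens: in the six complementarity-determining regions (CDRs L1–L3, H1–H3)
and in the relative orientation of the light and heavy variable domains
(V<sub>L</sub>–V<sub>H</sub>). Rigid-body docking of such models usually
fails because the paratope presented to the antigen is wrong. This package
implements a docking protocol that treats those error-prone degrees of
freedom as *sampled* variables: during each docking trajectory it
simultaneously optimizes

* the antibody–antigen rigid-body placement,
* the V<sub>L</sub>–V<sub>H</sub> orientation, and
* the CDR loop backbones (explicit H2/H3 perturbation plus all-CDR
  minimization),

optionally selecting among an ensemble of input antibody conformers
(conformer-selection docking). It also ships the standard docking
evaluation stack: ligand rmsd (L_rms), interface rmsd (I_rms), fraction of
native contacts (f_nat), CAPRI-style high/medium/acceptable/incorrect
ratings, and energy-funnel detection.

## The protocol

One decoy is one independent trajectory:

1. **Start** — local mode: spin the antigen uniformly about the axis of
   centers, tilt (σ = 8°) and translate (σ = 8 Å) along it; global mode:
   uniform random antigen orientation with the paratope re-aimed at the
   antigen.
2. **Slide into contact** — translate along the centers axis until the first
   antibody–antigen atom pair comes within 1 Å of van der Waals contact.
3. **Low-resolution stage** (centroid representation, side chains as single
   pseudo-atoms): 50 cycles of antibody rigid-body perturbation with
   Metropolis acceptance, plus optional Monte Carlo conformer swapping from
   the ensemble; then H2 and H3 relaxation by small/shear moves and cyclic
   coordinate descent (CCD) loop closure with the V_L–V_H jump frozen.
4. **Resolution switch** — side chains grafted back from the input
   structures; interface and CDR-neighborhood side chains packed.
5. **High-resolution stage** — 50 Monte Carlo iterations. Each draws one
   move from the set {antigen rigid body 40%, V_L–V_H rigid body 40%,
   all-CDR backbone minimization 10%, H3 relax 5%, H2 relax 5%}, packs the
   relevant side chains, minimizes the single degree of freedom just moved
   (isolated-DOF minimization), and accepts or rejects at kT = 0.8.
6. **Output** — the lowest *interface-energy* structure observed anywhere in
   the trajectory (interface energy = the antibody–antigen cross-partner
   component of the score, used to rank decoys).

Kinematics use fold trees: flexible jumps for the two rigid-body degrees of
freedom, and for loop moves fixed jumps across the loop stems with a
cutpoint at the loop middle, so torsion changes stay local and the mismatch
at the cut is measured as a chainbreak deviation and removed by CCD.

The scoring function is a transparent analog (soft-sphere repulsion,
Gaussian contact well, optional distance-dependent-dielectric Coulomb term,
chainbreak penalty, separate antibody–antigen and V_L–V_H interfacial
terms); see `docs/methods.md` for the exact forms and defaults.

## Worked example

Everything is runnable without any input downloads: the `fixtures` module
generates toy antibody-like complexes programmatically.

```python
import numpy as np
from snugdock import (
    FixtureSpec, ProtocolConfig, evaluate_decoy, make_homology_mimic,
    make_toy_complex, rank_decoys, run_simulation,
)

native, paratope = make_toy_complex()
mimic, ensemble = make_homology_mimic(native, paratope,
                                      FixtureSpec(homology_error=2.0))

cfg = ProtocolConfig(n_decoys=20, low_res_cycles=20, high_res_cycles=20,
                     min_max_iter=5, seed=11)
decoys = run_simulation(mimic, None, paratope, cfg)
for d in rank_decoys(decoys, k=3):
    rep = evaluate_decoy(d.best_pose, native)
    print(f"decoy {d.index:3d}  iface {d.energy.interface_energy:8.1f}  "
          f"L {rep.ligand_rmsd:5.2f}  I {rep.interface_rmsd:5.2f}  "
          f"fnat {rep.fnat:.2f}  {rep.rating.label}")
```

Output from the run above:

```
decoy  12  iface   -931.7  L 13.79  I  5.30  fnat 0.36  incorrect
decoy   8  iface   -790.3  L 15.39  I  6.59  fnat 0.25  incorrect
decoy  11  iface   -772.5  L 14.18  I  5.50  fnat 0.36  incorrect
```

Each row is one candidate complex ranked by interface energy; `L`/`I` are
ligand and interface rmsd to the native fixture in Å, `fnat` the fraction of
native residue–residue contacts recovered, and the last column the CAPRI
rating. (On this 20-decoy demo the three lowest-energy decoys are off-site;
the medium-quality decoys appear immediately below them in the ranking —
run `rank_decoys(decoys, k=10)` to see the funnel forming.)

A command-line interface mirrors the library:

```bash
snugdock make-fixture --seed 0 --out fixture/
snugdock dock --antibody ab.pdb --antigen ag.pdb --config cfg.yaml \
              --mode local --n-decoys 100 --seed 1 --out run/
snugdock evaluate --models run/ --native fixture/native.pdb \
                  --config cfg.yaml --out metrics.tsv
```

`cfg.yaml` names the chains (`partition:`) and the six CDR ranges
(`loops:`); `snugdock make-fixture` writes a ready-made `manifest.json` with
both blocks.

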