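"""The decoy-generation pipeline.

One decoy = one independent Monte Carlo trajectory: random start (local
perturbation or global randomization), slide into contact, a coarse-grained
stage of antibody rigid-body perturbations (with optional ensemble conformer
swapping), low-resolution H2+H3 loop relaxation with the V_L-V_H jump frozen,
recovery of full-atom side chains, interface packing, and a high-resolution
refinement stage that draws from a five-move set (antigen rigid body 40%,
V_L-V_H rigid body 40%, all-CDR backbone minimization 10%, H3 relaxation 5%,
H2 relaxation 5%), packs the relevant side chains, minimizes the isolated
degree of freedom just moved, and applies the Metropolis criterion at
kT = 0.8.  The lowest-interface-energy snapshot observed anywhere in the
trajectory is the decoy's output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .antibody import ParatopeMap, interface_residues
from .energetics import (
    EnergyReport, ScoreWeights, metropolis_accept, minimize, pack_sidechains, score,
)
from .kinematics import MoveMap, build_docking_foldtree, build_loop_foldtree
from .moves import (
    MoveSpec, PerturbParams, conformer_swap, default_move_specs,
    global_randomize_start, local_perturb_start, loop_relax, rigid_body_perturb,
    select_move, slide_into_contact,
)
from .structure import Pose, to_centroid, to_fullatom

logger = logging.getLogger("snugdock")


@dataclass
class ProtocolConfig:
    mode: str = "local"              # local | global
    n_decoys: int | None = None      # defaults: 1000 local, 5000 global
    low_res_cycles: int = 50
    high_res_cycles: int = 50
    kT: float = 0.8
    move_specs: list[MoveSpec] = field(default_factory=default_move_specs)
    perturb: PerturbParams = field(default_factory=PerturbParams)
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    seed: int = 0
    #: small/shear cycles per loop relaxation
    n_small: int = 5
    n_shear: int = 5
    #: coordinate-descent iteration budget for the isolated-DOF minimizer
    min_max_iter: int = 15
    #: run the low-res loop relaxation inside each cycle instead of once after
    lowres_loop_each_cycle: bool = False
    neighbor_cutoff: float = 8.0

    def __post_init__(self):
        if self.mode not in ("local", "global"):
            raise ValueError("mode must be local or global")
        if self.low_res_cycles <= 0 or self.high_res_cycles <= 0:
            raise ValueError("cycle counts must be positive")
        if self.kT <= 0:
            raise ValueError("kT must be positive")

    @property
    def effective_n_decoys(self) -> int:
        if self.n_decoys is not None:
            return self.n_decoys
        return 1000 if self.mode == "local" else 5000


@dataclass
class Decoy:
    index: int
    pose: Pose                # final accepted state
    best_pose: Pose           # lowest-interface-energy snapshot
    energy: EnergyReport      # score of best_pose
    trajectory_stats: dict


@dataclass
class DecoySet:
    decoys: list[Decoy]
    table: pd.DataFrame


def combine(antibody: Pose, antigen: Pose) -> Pose:
    """Merge separate antibody and antigen poses into one docking pose."""
    chains = {c: [r.copy() for r in rs] for c, rs in antibody.chains.items()}
    partition = {c: antibody.partition[c] for c in antibody.chains}
    for c, rs in antigen.chains.items():
        if c in chains:
            raise ValueError(f"duplicate chain id {c!r}")
        chains[c] = [r.copy() for r in rs]
        partition[c] = "antigen"
    return Pose(chains, partition, resolution=antibody.resolution)


def _neighbor_residues(pose: Pose, seeds, cutoff: float):
    """Residues whose CB (CA for glycine) lies within ``cutoff`` of any seed
    residue's CB/CA."""
    def probe(res):
        return res.atom("CB").coord if res.has_atom("CB") else res.atom("CA").coord

    seed_pts = [probe(pose.residue(c, n)) for c, n in seeds]
    if not seed_pts:
        return set(seeds)
    seed_pts = np.array(seed_pts)
    out = set(seeds)
    for cid, res in pose.iter_residues():
        p = probe(res)
        if np.min(np.linalg.norm(seed_pts - p, axis=1)) <= cutoff:
            out.add((cid, res.number))
    return out


def run_decoy(antibody: Pose | list[Pose], antigen: Pose | None,
              paratope: ParatopeMap, config: ProtocolConfig,
              seed: int, instrument: bool = False) -> Decoy:
    """Generate one decoy.

    ``antibody`` may be a single pose or an ensemble (first member starts the
    trajectory; the rest feed conformer swapping).  ``antigen`` may be None if
    the antibody pose already contains the antigen chains.
    """
    rng = np.random.default_rng(seed)
    ensemble = list(antibody) if isinstance(antibody, (list, tuple)) else [antibody]
    start = ensemble[0]
    pose = combine(start, antigen) if antigen is not None else start.copy()
    pose.validate()
    if pose.resolution != "fullatom":
        raise ValueError("run_decoy expects full-atom input")
    donor_full = pose.copy()
    w = config.weights
    stats = {"low_res_cycles": 0, "high_res_cycles": 0, "swaps_tried": 0,
             "moves_tried": {n: 0 for n in ("dock_rb", "vlvh_rb", "cdr_min",
                                            "h3_relax", "h2_relax")},
             "moves_accepted": {n: 0 for n in ("dock_rb", "vlvh_rb", "cdr_min",
                                               "h3_relax", "h2_relax")},
             "steps": []}

    def log_step(name):
        if instrument:
            stats["steps"].append(name)

    # ---- low resolution -------------------------------------------------
    cen = to_centroid(pose)
    dock_tree = build_docking_foldtree(cen)
    loop_tree_frozen = build_loop_foldtree(cen, paratope.loops, allow_vl_vh=False)

    if config.mode == "local":
        cen = local_perturb_start(cen, config.perturb, rng)
    else:
        cen = global_randomize_start(cen, paratope, rng)
    log_step("init")
    cen = slide_into_contact(cen)
    log_step("slide")

    cen_ensemble = None
    if len(ensemble) > 1:
        cen_ensemble = [to_centroid(p) for p in ensemble]

    e_cen = score(cen, w, loop_tree_frozen).total
    for _ in range(config.low_res_cycles):
        stats["low_res_cycles"] += 1
        cand = rigid_body_perturb(cen, dock_tree, "dock",
                                  config.perturb.lowres_trans,
                                  config.perturb.lowres_rot, rng)
        e_new = score(cand, w, loop_tree_frozen).total
        if metropolis_accept(e_new - e_cen, config.kT, rng):
            cen, e_cen = cand, e_new
        if cen_ensemble is not None:
            stats["swaps_tried"] += 1
            cen = conformer_swap(cen, cen_ensemble, config.kT, rng, w,
                                 loop_tree_frozen)
            e_cen = score(cen, w, loop_tree_frozen).total
        log_step("lowres_cycle")
        if config.lowres_loop_each_cycle:
            for loop_name in ("H2", "H3"):
                cen, _ = loop_relax(cen, loop_tree_frozen,
                                    paratope.loop(loop_name), rng,
                                    n_small=config.n_small, n_shear=config.n_shear)
            e_cen = score(cen, w, loop_tree_frozen).total

    if not config.lowres_loop_each_cycle:
        for loop_name in ("H2", "H3"):
            cen, _ = loop_relax(cen, loop_tree_frozen, paratope.loop(loop_name),
                                rng, n_small=config.n_small, n_shear=config.n_shear)
        log_step("lowres_loops")

    # ---- resolution switch ----------------------------------------------
    pose = to_fullatom(cen, {c: donor_full for c in donor_full.chains})
    log_step("to_fullatom")
    dock_tree = build_docking_foldtree(pose)
    loop_tree = build_loop_foldtree(pose, paratope.loops, allow_vl_vh=False)

    ab_iface, ag_iface = _interface_or_empty(pose)
    cdr_neigh = _neighbor_residues(pose, paratope.paratope, config.neighbor_cutoff)
    vl, vh = _vlvh_interface_or_empty(pose)
    pose = pack_sidechains(pose, ab_iface | ag_iface | vl | vh | cdr_neigh, rng, w)
    log_step("pack_all")

    # ---- high resolution -------------------------------------------------
    e_cur = score(pose, w, loop_tree)
    best_pose, best_energy = pose.copy(), e_cur
    for _ in range(config.high_res_cycles):
        stats["high_res_cycles"] += 1
        spec = select_move(config.move_specs, rng)
        stats["moves_tried"][spec.name] += 1
        cand = _apply_high_res_move(pose, spec, paratope, config, dock_tree,
                                    loop_tree, rng)
        e_new = score(cand, w, loop_tree)
        if metropolis_accept(e_new.total - e_cur.total, config.kT, rng):
            pose, e_cur = cand, e_new
            stats["moves_accepted"][spec.name] += 1
        if e_cur.interface_energy < best_energy.interface_energy:
            best_pose, best_energy = pose.copy(), e_cur
        log_step(f"highres_{spec.name}")

    return Decoy(index=seed, pose=pose, best_pose=best_pose,
                 energy=best_energy, trajectory_stats=stats)


def _interface_or_empty(pose: Pose):
    try:
        return interface_residues(pose, pose.antibody_chains,
                                  pose.antigen_chains, 10.0)
    except ValueError:
        return set(), set()


def _vlvh_interface_or_empty(pose: Pose):
    try:
        return interface_residues(pose, pose.chain_ids("light"),
                                  pose.chain_ids("heavy"), 10.0)
    except ValueError:
        return set(), set()


def _apply_high_res_move(pose: Pose, spec: MoveSpec, paratope: ParatopeMap,
                         config: ProtocolConfig, dock_tree, loop_tree,
                         rng: np.random.Generator) -> Pose:
    w = config.weights
    p = config.perturb
    if spec.name in ("dock_rb", "vlvh_rb"):
        jump = "dock" if spec.name == "dock_rb" else "vl_vh"
        cand = rigid_body_perturb(pose, dock_tree, jump, p.trans_sigma,
                                  p.rot_sigma, rng)
        if spec.name == "dock_rb":
            a, b = _interface_or_empty(cand)
        else:
            a, b = _vlvh_interface_or_empty(cand)
        cand = pack_sidechains(cand, a | b, rng, w)
        mm = MoveMap(jumps_free={jump})
        return minimize(cand, dock_tree, mm, w, max_iter=config.min_max_iter)
    if spec.name == "cdr_min":
        mm = MoveMap(backbone_free=set(paratope.paratope))
        cand = minimize(pose, loop_tree, mm, w, max_iter=config.min_max_iter)
        sel = _neighbor_residues(cand, paratope.paratope, config.neighbor_cutoff)
        cand = pack_sidechains(cand, sel, rng, w)
        return minimize(cand, loop_tree, mm, w, max_iter=config.min_max_iter)
    # h3_relax / h2_relax: relaxation includes its own minimization; no extra
    # minimization afterwards
    loop = paratope.loop("H3" if spec.name == "h3_relax" else "H2")
    cand, _ = loop_relax(pose, loop_tree, loop, rng, n_small=config.n_small,
                         n_shear=config.n_shear, minimize_after=True,
                         weights=w, min_max_iter=config.min_max_iter)
    sel = _neighbor_residues(cand, {(loop.chain, i) for i in loop.residues()},
                             config.neighbor_cutoff)
    return pack_sidechains(cand, sel, rng, w)


def run_simulation(antibody, antigen, paratope: ParatopeMap,
                   config: ProtocolConfig) -> DecoySet:
    """Generate ``config.effective_n_decoys`` independent decoys; decoy k uses
    seed ``config.seed + k`` so batches are reproducible and trivially
    parallel.  Per-decoy failures are logged and skipped."""
    decoys = []
    rows = []
    for k in range(config.effective_n_decoys):
        seed = config.seed + k
        try:
            d = run_decoy(antibody, antigen, paratope, config, seed)
        except Exception as exc:  # pragma: no cover - defensive batch behavior
            logger.error("decoy %d failed: %s", k, exc)
            continue
        d.index = k
        decoys.append(d)
        row = {"decoy": k, "seed": seed, "total": d.energy.total,
               "interface_energy": d.energy.interface_energy}
        row.update({f"term_{t}": v for t, v in d.energy.terms.items()})
        rows.append(row)
    return DecoySet(decoys=decoys, table=pd.DataFrame(rows))


def rank_decoys(decoy_set: DecoySet, by: str = "interface_energy",
                k: int | None = None) -> list[Decoy]:
    """Stable ascending ranking by interface energy (default) or total score;
    ties keep decoy order."""
    if not decoy_set.decoys:
        raise ValueError("empty decoy set")
    if by not in ("interface_energy", "total"):
        raise ValueError("rank key must be interface_energy or total")
    key = (lambda d: d.energy.interface_energy) if by == "interface_energy" \
        else (lambda d: d.energy.total)
    ranked = sorted(decoy_set.decoys, key=key)  # sorted() is stable
    if k is None:
        return ranked
    if k > len(ranked):
        logger.warning("requested top %d of %d decoys; returning all",
                       k, len(ranked))
    return ranked[:k]
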