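"""Scoring, Metropolis acceptance, isolated-DOF minimization and packing.

The score function is a transparent analog of a coarse docking potential,
fully specified here rather than inherited from any external force field:

* soft-sphere repulsion  ``max(0, (r_ij - d)/r_ij)^2``  per heavy-atom pair,
  where ``r_ij`` is the sum of the two van der Waals radii;
* a Gaussian contact well  ``-exp(-(d - r_ij)^2 / (2 sigma^2))``, sigma 1.5 A,
  rewarding surface complementarity;
* optional Coulomb electrostatics with a distance-dependent dielectric
  (epsilon = 4d) over a small formal-charge table;
* a chainbreak penalty ``weight * deviation^2`` per CDR cutpoint;
* the two interfacial components (antibody-antigen and V_L-V_H cross-partner
  pair energies) carried as separate terms so they can be weighted and so the
  antibody-antigen component -- the "interface energy" used to rank decoys --
  is available exactly.

Pairs within one residue or between chain-adjacent residues are excluded;
everything runs over non-hydrogen (or pseudo) atoms within a 12 A cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import rotation_about_axis
from .kinematics import FoldTree, MoveMap, apply_jump, set_backbone_torsion, total_chainbreak
from .structure import Pose

logger = logging.getLogger("snugdock")

PAIR_CUTOFF = 12.0
CONTACT_SIGMA = 1.5
COULOMB_K = 332.0  # kcal*A/(mol*e^2); dielectric 4d makes the term k*q1*q2/(4 d^2)

#: formal charges by atom name (terminal side-chain groups only)
ATOM_CHARGES = {"NZ": 1.0, "OE1": -1.0, "OD1": -1.0, "NE": 0.5, "CZ": 0.5}


@dataclass(frozen=True)
class ScoreWeights:
    vdw_repulsive: float = 1.0
    contact_attractive: float = 0.5
    electrostatic: float = 0.25
    chainbreak: float = 10.0
    interchain_ab_ag: float = 1.0
    interchain_vl_vh: float = 1.0

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if not np.isfinite(v):
                raise ValueError(f"weight {name} must be finite")
        if self.chainbreak <= 0:
            raise ValueError("chainbreak weight must be > 0")

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


@dataclass
class EnergyReport:
    total: float
    terms: dict[str, float]
    interface_energy: float


def _flatten(pose: Pose):
    """Flat heavy-atom arrays: coords, radii, charges, body id
    (0 light / 1 heavy / 2 antigen), chain index and residue position."""
    body_of = {"light": 0, "heavy": 1, "antigen": 2}
    coords, radii, charges, bodies, chain_idx, res_pos = [], [], [], [], [], []
    for ci, (cid, residues) in enumerate(pose.chains.items()):
        b = body_of[pose.partition[cid]]
        for pos, res in enumerate(residues):
            for a in res.atoms:
                if a.is_hydrogen:
                    continue
                coords.append(a.coord)
                radii.append(a.vdw_radius)
                charges.append(ATOM_CHARGES.get(a.name, 0.0))
                bodies.append(b)
                chain_idx.append(ci)
                res_pos.append(pos)
    return (np.array(coords), np.array(radii), np.array(charges),
            np.array(bodies), np.array(chain_idx), np.array(res_pos))


def score(pose: Pose, weights: ScoreWeights | None = None,
          tree: FoldTree | None = None) -> EnergyReport:
    """Deterministic decomposed score; ``tree`` supplies the cutpoints for the
    chainbreak term (no tree -> no chainbreak)."""
    weights = weights or ScoreWeights()
    coords, radii, charges, bodies, chain_idx, res_pos = _flatten(pose)
    if not np.all(np.isfinite(coords)):
        raise ValueError("pose contains non-finite coordinates")

    pairs = cKDTree(coords).query_pairs(PAIR_CUTOFF, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        same_chain = chain_idx[i] == chain_idx[j]
        bonded = same_chain & (np.abs(res_pos[i] - res_pos[j]) <= 1)
        keep = ~bonded
        i, j = i[keep], j[keep]
    else:
        i = j = np.empty(0, dtype=int)

    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    rsum = radii[i] + radii[j]
    rep = np.square(np.maximum(0.0, (rsum - d) / rsum))
    att = -np.exp(-np.square(d - rsum) / (2.0 * CONTACT_SIGMA**2))
    qq = charges[i] * charges[j]
    with np.errstate(divide="ignore"):
        elec = np.where(qq != 0.0, COULOMB_K * qq / (4.0 * np.square(d)), 0.0)

    cross_ab_ag = (bodies[i] == 2) != (bodies[j] == 2)
    cross_vl_vh = ((bodies[i] == 0) & (bodies[j] == 1)) | ((bodies[i] == 1) & (bodies[j] == 0))
    intra = ~(cross_ab_ag | cross_vl_vh)

    def pair_energy(mask) -> float:
        return float(weights.vdw_repulsive * rep[mask].sum()
                     + weights.contact_attractive * att[mask].sum()
                     + weights.electrostatic * elec[mask].sum())

    cb = total_chainbreak(pose, tree) if tree is not None else 0.0
    terms = {
        "vdw_repulsive": float(rep[intra].sum()),
        "contact_attractive": float(att[intra].sum()),
        "electrostatic": float(elec[intra].sum()),
        "chainbreak": cb,
        "interchain_ab_ag": pair_energy(cross_ab_ag),
        "interchain_vl_vh": pair_energy(cross_vl_vh),
    }
    total = (weights.vdw_repulsive * terms["vdw_repulsive"]
             + weights.contact_attractive * terms["contact_attractive"]
             + weights.electrostatic * terms["electrostatic"]
             + weights.chainbreak * terms["chainbreak"]
             + weights.interchain_ab_ag * terms["interchain_ab_ag"]
             + weights.interchain_vl_vh * terms["interchain_vl_vh"])
    return EnergyReport(total=total, terms=terms,
                        interface_energy=weights.interchain_ab_ag * terms["interchain_ab_ag"])


def metropolis_accept(delta_e: float, kT: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: downhill always accepted, uphill with Boltzmann
    probability exp(-delta_e / kT)."""
    if kT <= 0:
        raise ValueError("kT must be positive")
    if delta_e <= 0:
        return True
    if not np.isfinite(delta_e):
        return False
    return bool(rng.random() < np.exp(-delta_e / kT))


# ---- isolated-DOF minimization ----------------------------------------


class _SubsetObjective:
    """Total-score objective specialized for a minimization where only a known
    set of residues/chains can move.

    The static-static interaction energy is computed once; each evaluation
    recomputes only moving-moving and moving-static pairs (plus chainbreak),
    so the value always equals the full ``score(...).total`` up to float
    round-off while costing a fraction of it.
    """

    def __init__(self, pose: Pose, weights: ScoreWeights, tree: FoldTree | None,
                 moving_chains=(), moving_residues=()):
        self.weights = weights
        self.tree = tree
        self.pose = pose
        moving_chains = set(moving_chains)
        moving_residues = set(moving_residues)

        self.atoms = []
        radii, charges, bodies, chain_idx, res_pos, mov = [], [], [], [], [], []
        body_of = {"light": 0, "heavy": 1, "antigen": 2}
        for ci, (cid, residues) in enumerate(pose.chains.items()):
            b = body_of[pose.partition[cid]]
            for pos, res in enumerate(residues):
                is_mov = cid in moving_chains or (cid, res.number) in moving_residues
                for a in res.atoms:
                    if a.is_hydrogen:
                        continue
                    self.atoms.append(a)
                    radii.append(a.vdw_radius)
                    charges.append(ATOM_CHARGES.get(a.name, 0.0))
                    bodies.append(b)
                    chain_idx.append(ci)
                    res_pos.append(pos)
                    mov.append(is_mov)
        radii = np.array(radii); charges = np.array(charges)
        bodies = np.array(bodies); chain_idx = np.array(chain_idx)
        res_pos = np.array(res_pos); mov = np.array(mov, dtype=bool)

        mov_idx = np.where(mov)[0]
        stat_idx = np.where(~mov)[0]
        self._mov_atoms = [self.atoms[k] for k in mov_idx]
        self._stat_coords = np.array([self.atoms[k].coord for k in stat_idx]) \
            if len(stat_idx) else np.empty((0, 3))

        def pair_weight_class(i, j):
            cross_ab_ag = (bodies[i] == 2) != (bodies[j] == 2)
            cross_vl_vh = ((bodies[i] == 0) & (bodies[j] == 1)) | \
                          ((bodies[i] == 1) & (bodies[j] == 0))
            wfac = np.ones(len(i))
            wfac[cross_ab_ag] = weights.interchain_ab_ag
            wfac[cross_vl_vh] = weights.interchain_vl_vh
            return wfac

        coords0 = np.array([a.coord for a in self.atoms])

        def pair_list(idx_a, idx_b, upper_triangle):
            ia, ib = np.meshgrid(idx_a, idx_b, indexing="ij")
            ia, ib = ia.ravel(), ib.ravel()
            if upper_triangle:
                keep = ia < ib
                ia, ib = ia[keep], ib[keep]
            bonded = (chain_idx[ia] == chain_idx[ib]) & \
                     (np.abs(res_pos[ia] - res_pos[ib]) <= 1)
            ia, ib = ia[~bonded], ib[~bonded]
            # neighbor list: drop pairs that start far beyond the cutoff and
            # cannot plausibly enter it during one isolated-DOF minimization
            d0 = np.linalg.norm(coords0[ia] - coords0[ib], axis=1)
            near = d0 < PAIR_CUTOFF + self.NEIGHBOR_MARGIN
            return ia[near], ib[near]

        mm = pair_list(mov_idx, mov_idx, True)
        ms = pair_list(mov_idx, stat_idx, False)
        mov_local = {g: l for l, g in enumerate(mov_idx)}
        stat_local = {g: l for l, g in enumerate(stat_idx)}
        self._mm = (np.array([mov_local[g] for g in mm[0]], dtype=int),
                    np.array([mov_local[g] for g in mm[1]], dtype=int))
        self._ms = (np.array([mov_local[g] for g in ms[0]], dtype=int),
                    np.array([stat_local[g] for g in ms[1]], dtype=int))
        self._mm_w = pair_weight_class(*mm)
        self._ms_w = pair_weight_class(*ms)
        self._mm_rsum = radii[mm[0]] + radii[mm[1]]
        self._ms_rsum = radii[ms[0]] + radii[ms[1]]
        self._mm_qq = charges[mm[0]] * charges[mm[1]]
        self._ms_qq = charges[ms[0]] * charges[ms[1]]

        # static part computed once from the full score minus subset part
        self._static = 0.0
        full = score(pose, weights, tree).total
        self._static = full - self._subset_energy() - self._chainbreak()

    #: pairs farther than cutoff + margin at construction are ignored
    NEIGHBOR_MARGIN = 6.0

    def _chainbreak(self) -> float:
        if self.tree is None:
            return 0.0
        return self.weights.chainbreak * total_chainbreak(self.pose, self.tree)

    def _pair_sum(self, diff, rsum, qq, wfac) -> float:
        if len(rsum) == 0:
            return 0.0
        d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        within = d < PAIR_CUTOFF
        d, rs, q, wf = d[within], rsum[within], qq[within], wfac[within]
        rep = np.square(np.maximum(0.0, (rs - d) / rs))
        att = -np.exp(-np.square(d - rs) / (2.0 * CONTACT_SIGMA**2))
        e = (self.weights.vdw_repulsive * rep
             + self.weights.contact_attractive * att)
        nz = q != 0.0
        if np.any(nz):
            e[nz] += self.weights.electrostatic * COULOMB_K * q[nz] / (4.0 * np.square(d[nz]))
        return float((e * wf).sum())

    def _subset_energy(self) -> float:
        mc = np.array([a.coord for a in self._mov_atoms])
        e = self._pair_sum(mc[self._mm[0]] - mc[self._mm[1]],
                           self._mm_rsum, self._mm_qq, self._mm_w)
        e += self._pair_sum(mc[self._ms[0]] - self._stat_coords[self._ms[1]],
                            self._ms_rsum, self._ms_qq, self._ms_w)
        return e

    def total(self) -> float:
        return self._static + self._subset_energy() + self._chainbreak()


def _jump_dofs(pose: Pose, tree: FoldTree, jump_name: str):
    """Six coordinate-descent DOFs (3 translations, 3 rotations about the
    downstream center of mass) for one jump."""
    axes = np.eye(3)

    def make_trans(axis):
        def apply(p: Pose, step: float):
            apply_jump(p, tree, jump_name, np.eye(3), step * axis)
        return apply

    def make_rot(axis):
        def apply(p: Pose, step: float):
            apply_jump(p, tree, jump_name, rotation_about_axis(axis, step), np.zeros(3))
        return apply

    dofs = [(make_trans(a), 0.2) for a in axes]
    dofs += [(make_rot(a), 2.0) for a in axes]
    return dofs


def _torsion_dofs(pose: Pose, tree: FoldTree, residues):
    def make(chain, number, angle):
        def apply(p: Pose, step: float):
            pos = p.residue_index(chain, number)
            cur = p.backbone_torsion(chain, pos, angle)
            set_backbone_torsion(p, tree, chain, number, angle, cur + step)
        return apply

    dofs = []
    for chain, number in residues:
        pos = None
        for angle in ("phi", "psi"):
            try:
                # probe that the torsion is defined
                pos = pose.residue_index(chain, number)
                pose.backbone_torsion(chain, pos, angle)
            except (ValueError, KeyError):
                continue
            dofs.append((make(chain, number, angle), 5.0))
    return dofs


def minimize(pose: Pose, tree: FoldTree, movemap: MoveMap,
             weights: ScoreWeights | None = None, max_iter: int = 50,
             tol: float = 1e-4) -> Pose:
    """Derivative-free coordinate descent over the move map's DOFs with
    per-DOF adaptive steps (halved on failure).  Monotone: a trial step is
    kept only if it lowers the total score, so the returned pose never scores
    above the input.  Frozen DOFs are never touched."""
    weights = weights or ScoreWeights()
    out = pose.copy()
    dofs = []
    moving_chains: set[str] = set()
    for jname in sorted(movemap.jumps_free):
        dofs.extend(_jump_dofs(out, tree, jname))
        moving_chains |= set(tree.jump(jname).downstream)
    moving_residues: set[tuple[str, int]] = set()
    if movemap.backbone_free:
        dofs.extend(_torsion_dofs(out, tree, sorted(movemap.backbone_free)))
        for chain, number in movemap.backbone_free:
            lp = tree.loop_for(chain, number)
            if lp is not None:
                moving_residues |= {(lp.chain, i) for i in lp.residues()}
            else:
                moving_residues |= {(chain, r.number) for r in out.chains[chain]
                                    if r.number >= number}
    if not dofs:
        logger.warning("minimize: empty move map; no-op")
        return out

    objective = _SubsetObjective(out, weights, tree, moving_chains, moving_residues)
    steps = [s for _, s in dofs]
    e0 = objective.total()
    for _ in range(max_iter):
        improved = 0.0
        for k, (apply_step, _) in enumerate(dofs):
            if steps[k] < 1e-6:
                continue
            moved = False
            for direction in (+1.0, -1.0):
                apply_step(out, direction * steps[k])
                e1 = objective.total()
                if e1 < e0 - 1e-12:
                    improved += e0 - e1
                    e0 = e1
                    moved = True
                    break
                apply_step(out, -direction * steps[k])  # revert
            if not moved:
                steps[k] *= 0.5
        if improved < tol:
            break
    return out


# ---- side-chain packing ------------------------------------------------


def _chi_chain(res):
    """Linear side-chain heavy-atom chain rooted at CA (the toy residues and
    internal templates are unbranched); returns [CA, CB, CG, ...] coords refs."""
    side = res.sidechain_atoms()
    side = [a for a in side if a.name != "CEN"]
    return [res.atom("CA")] + side


def _local_pair_energy(moving: np.ndarray, context: np.ndarray,
                       mov_r: np.ndarray, ctx_r: np.ndarray,
                       weights: ScoreWeights) -> float:
    if len(moving) == 0 or len(context) == 0:
        return 0.0
    d = np.linalg.norm(moving[:, None, :] - context[None, :, :], axis=2)
    rsum = mov_r[:, None] + ctx_r[None, :]
    mask = d < PAIR_CUTOFF
    rep = np.square(np.maximum(0.0, (rsum - d) / rsum))
    att = -np.exp(-np.square(d - rsum) / (2.0 * CONTACT_SIGMA**2))
    return float((weights.vdw_repulsive * rep + weights.contact_attractive * att)[mask].sum())


def pack_sidechains(pose: Pose, residues, rng: np.random.Generator,
                    weights: ScoreWeights | None = None) -> Pose:
    """Greedy one-sweep chi-grid optimization of the selected residues'
    side chains (30 deg grid then 10 deg refinement), in random residue
    order.  Backbone atoms never move."""
    if pose.resolution != "fullatom":
        raise ValueError("pack_sidechains requires a full-atom pose")
    weights = weights or ScoreWeights()
    out = pose.copy()
    residues = sorted(residues)
    if not residues:
        return out
    order = [residues[k] for k in rng.permutation(len(residues))]

    # static context: every heavy atom not belonging to the residue being packed
    all_atoms = [(cid, res, a) for cid, res, a in out.iter_atoms() if not a.is_hydrogen]

    for chain, number in order:
        res = out.residue(chain, number)
        chain_atoms = _chi_chain(res)
        if len(chain_atoms) < 3:
            continue  # no rotatable chi (GLY/ALA)
        ctx = np.array([a.coord for cid, r, a in all_atoms
                        if not (cid == chain and r is res)])
        ctx_r = np.array([a.vdw_radius for cid, r, a in all_atoms
                          if not (cid == chain and r is res)])
        n_chi = len(chain_atoms) - 2
        for k in range(1, n_chi + 1):
            pivot_prev = chain_atoms[k - 1].coord
            pivot = chain_atoms[k].coord
            moving_atoms = chain_atoms[k + 1:]
            axis = pivot - pivot_prev

            def energy_at(delta_deg: float) -> float:
                R = rotation_about_axis(axis, delta_deg)
                pts = np.array([a.coord for a in moving_atoms])
                pts = (pts - pivot) @ R.T + pivot
                return _local_pair_energy(pts, ctx,
                                          np.array([a.vdw_radius for a in moving_atoms]),
                                          ctx_r, weights)

            best_delta, best_e = 0.0, energy_at(0.0)
            for delta in np.arange(-180.0, 180.0, 30.0):
                e = energy_at(delta)
                if e < best_e - 1e-12:
                    best_delta, best_e = delta, e
            for delta in np.arange(best_delta - 30.0, best_delta + 30.0 + 1e-9, 10.0):
                e = energy_at(delta)
                if e < best_e - 1e-12:
                    best_delta, best_e = delta, e
            if best_delta != 0.0:
                R = rotation_about_axis(axis, best_delta)
                for a in moving_atoms:
                    a.coord = R @ (a.coord - pivot) + pivot
    return out
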