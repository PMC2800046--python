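"""Fold-tree kinematics: rigid-body jumps, torsion propagation and cutpoints.

Two trees cover the whole protocol.  The docking tree connects the light
chain, the heavy chain and the antigen through two flexible 6-DOF jumps
(light<->heavy and antibody<->antigen) with no cutpoints, so rigid-body moves
act on whole bodies and torsion moves would propagate to chain ends.  The
loop tree places a fixed jump across each CDR loop's stems and a cutpoint at
the loop middle, so loop torsion moves stay local: the N-terminal half of a
loop builds forward from the start stem, the C-terminal half builds backward
from the stop stem, and the mismatch across the cut is measured as a
chainbreak deviation and removed by CCD closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .antibody import LoopDefinition
from .geometry import (
    ANGLE_CA_C_N,
    BOND_C_N,
    normalize,
    rotate_points_about_line,
)
from .structure import Pose


@dataclass(frozen=True)
class Jump:
    """6-DOF rigid connection: moving the jump transforms every atom of the
    downstream chains about their center of mass."""

    jump_id: int
    name: str
    upstream: tuple[str, ...]
    downstream: tuple[str, ...]
    flexible: bool = True


@dataclass(frozen=True)
class Cutpoint:
    chain: str
    after_residue: int  # chain is severed between this residue and the next


@dataclass
class FoldTree:
    jumps: list[Jump] = field(default_factory=list)
    cutpoints: list[Cutpoint] = field(default_factory=list)
    #: loop definitions owning the cutpoints (loop trees only)
    loops: dict[str, LoopDefinition] = field(default_factory=dict)

    def jump(self, key) -> Jump:
        for j in self.jumps:
            if j.jump_id == key or j.name == key:
                return j
        raise KeyError(f"no jump {key!r}")

    def loop_for(self, chain: str, number: int) -> LoopDefinition | None:
        for lp in self.loops.values():
            if lp.chain == chain and lp.start <= number <= lp.stop:
                return lp
        return None


@dataclass
class MoveMap:
    """Which degrees of freedom a mover may touch."""

    backbone_free: set[tuple[str, int]] = field(default_factory=set)
    jumps_free: set[str] = field(default_factory=set)
    sidechain_free: set[tuple[str, int]] = field(default_factory=set)


def build_docking_foldtree(pose: Pose) -> FoldTree:
    """Two flexible jumps: light<->heavy (jump 1) and antibody<->antigen
    (jump 2); no cutpoints."""
    light = tuple(pose.chain_ids("light"))
    heavy = tuple(pose.chain_ids("heavy"))
    antigen = tuple(pose.chain_ids("antigen"))
    if not (light and heavy and antigen):
        raise ValueError("pose must have light, heavy and antigen chains")
    return FoldTree(jumps=[
        Jump(1, "vl_vh", light, heavy, flexible=True),
        Jump(2, "dock", light + heavy, antigen, flexible=True),
    ])


def build_loop_foldtree(pose: Pose, loops, allow_vl_vh: bool = False) -> FoldTree:
    """Fixed jump across each loop's stems (start-1 -> stop+1), cutpoint at the
    loop middle; the V_L-V_H jump is frozen unless ``allow_vl_vh``."""
    light = tuple(pose.chain_ids("light"))
    heavy = tuple(pose.chain_ids("heavy"))
    antigen = tuple(pose.chain_ids("antigen"))
    loop_map: dict[str, LoopDefinition] = {}
    cutpoints = []
    for lp in (loops.values() if isinstance(loops, dict) else loops):
        numbers = {r.number for r in pose.chains[lp.chain]}
        if lp.start - 1 not in numbers or lp.stop + 1 not in numbers:
            raise ValueError(f"loop {lp.name} lacks a stem residue on one side")
        loop_map[lp.name] = lp
        cutpoints.append(Cutpoint(lp.chain, lp.cutpoint))
    jumps = [
        Jump(1, "vl_vh", light, heavy, flexible=allow_vl_vh),
        Jump(2, "dock", light + heavy, antigen, flexible=True),
    ]
    return FoldTree(jumps=jumps, cutpoints=cutpoints, loops=loop_map)


def apply_jump(pose: Pose, tree: FoldTree, jump_key, R: np.ndarray,
               t: np.ndarray) -> None:
    """Rotate the downstream body about its own center of mass by ``R`` and
    translate by ``t`` (in place)."""
    j = tree.jump(jump_key)
    if not j.flexible:
        raise ValueError(f"jump {j.name!r} is frozen in this fold tree")
    com = pose.center_of_mass(list(j.downstream))
    pose.transform_chains(j.downstream, R, t + com - R @ com)


# ---- torsion propagation ----------------------------------------------

_TORSIONS = ("phi", "psi", "omega")


def _moving_atoms(pose: Pose, tree: FoldTree, chain: str, pos: int,
                  angle_name: str):
    """Atoms displaced by changing the named torsion, the rotation axis
    (origin, direction), and the sign of the applied rotation.

    Inside a cut loop, residues up to the cutpoint propagate forward (toward
    the cut) and residues after it propagate backward (toward the cut from the
    stop stem), so the stems never move.  Outside any loop, propagation runs
    forward to the chain end.
    """
    residues = pose.chains[chain]
    res = residues[pos]
    lp = tree.loop_for(chain, res.number)

    if lp is None:
        seg_first, seg_last, forward = pos, len(residues) - 1, True
    else:
        cut_pos = pose.residue_index(chain, lp.cutpoint)
        if pos <= cut_pos:
            seg_first, seg_last, forward = pos, cut_pos, True
        else:
            seg_first, seg_last, forward = cut_pos + 1, pos, False

    n, ca, c = (res.atom(x).coord for x in ("N", "CA", "C"))
    if angle_name == "phi":
        origin, axis = n, ca - n
        own_moving = [a for a in res.atoms if a.name not in ("N", "CA")]
        own_fixed_back = [res.atom("N")]
    elif angle_name == "psi":
        origin, axis = ca, c - ca
        own_moving = [a for a in res.atoms if a.name == "O"]
        own_fixed_back = [a for a in res.atoms if a.name not in ("CA", "C", "O")]
    elif angle_name == "omega":
        if pos == len(residues) - 1:
            raise ValueError("omega undefined for last residue")
        nxt = residues[pos + 1]
        origin, axis = c, nxt.atom("N").coord - c
        own_moving = []
        own_fixed_back = [a for a in res.atoms if a.name != "C"]
    else:
        raise ValueError(f"unknown torsion {angle_name!r}")

    atoms = []
    if forward:
        atoms.extend(own_moving)
        for r in residues[pos + 1:seg_last + 1]:
            atoms.extend(r.atoms)
        sign = 1.0
    else:
        # anchored at the C-terminal stem: the complementary branch rotates
        # by the negated angle about the same axis
        for r in residues[seg_first:pos]:
            atoms.extend(r.atoms)
        atoms.extend(own_fixed_back)
        sign = -1.0
    return atoms, origin, axis, sign


def set_backbone_torsion(pose: Pose, tree: FoldTree, chain: str, number: int,
                         angle_name: str, value: float,
                         movemap: MoveMap | None = None) -> None:
    """Set phi/psi/omega (degrees) in place, rebuilding Cartesian coordinates
    by rigid rotation about the bond axis; bond lengths and angles are
    untouched."""
    if movemap is not None and (chain, number) not in movemap.backbone_free:
        raise ValueError(f"residue {chain}{number} frozen in move map")
    pos = pose.residue_index(chain, number)
    current = pose.backbone_torsion(chain, pos, angle_name)
    delta = value - current
    if abs(delta) < 1e-12:
        return
    atoms, origin, axis, sign = _moving_atoms(pose, tree, chain, pos, angle_name)
    if not atoms:
        return
    pts = np.array([a.coord for a in atoms])
    pts = rotate_points_about_line(pts, origin, axis, sign * delta)
    for a, p in zip(atoms, pts):
        a.coord = p


def rotate_torsion_branch(pose: Pose, tree: FoldTree, chain: str, number: int,
                          angle_name: str, angle_deg: float) -> list:
    """Rotate the torsion's moving branch by exactly ``angle_deg`` about the
    bond axis (right-handed about the N->CA / CA->C / C->N direction),
    bypassing dihedral sign conventions.  Returns the atoms that moved.
    Used by the analytic CCD updates."""
    if abs(angle_deg) < 1e-12:
        return []
    pos = pose.residue_index(chain, number)
    atoms, origin, axis, _ = _moving_atoms(pose, tree, chain, pos, angle_name)
    if not atoms:
        return []
    pts = np.array([a.coord for a in atoms])
    pts = rotate_points_about_line(pts, origin, axis, angle_deg)
    for a, p in zip(atoms, pts):
        a.coord = p
    return atoms


def perturb_backbone_torsion(pose: Pose, tree: FoldTree, chain: str,
                             number: int, angle_name: str, delta: float,
                             movemap: MoveMap | None = None) -> None:
    pos = pose.residue_index(chain, number)
    current = pose.backbone_torsion(chain, pos, angle_name)
    target = current + delta
    while target > 180.0:
        target -= 360.0
    while target <= -180.0:
        target += 360.0
    set_backbone_torsion(pose, tree, chain, number, angle_name, target, movemap)


# ---- chainbreak --------------------------------------------------------


def chainbreak_deviation(pose: Pose, cutpoint: Cutpoint) -> float:
    """Euclidean mismatch (Angstrom) between the actual amide nitrogen after
    the cut and its ideal position implied by standard peptide geometry from
    the upstream residue (C-N 1.329 A, CA-C-N 116.2 deg); 0 for a perfectly
    closed loop and invariant under global rigid motion."""
    chain = pose.chains[cutpoint.chain]
    pos = pose.residue_index(cutpoint.chain, cutpoint.after_residue)
    if pos + 1 >= len(chain):
        raise ValueError("cutpoint at chain terminus")
    c = chain[pos].atom("C").coord
    ca = chain[pos].atom("CA").coord
    n_act = chain[pos + 1].atom("N").coord

    u = normalize(ca - c)
    w = n_act - c
    w_perp = w - np.dot(w, u) * u
    norm = np.linalg.norm(w_perp)
    if norm < 1e-8:
        # degenerate (collinear): fall back to pure bond-length mismatch
        return abs(float(np.linalg.norm(w)) - BOND_C_N)
    w_perp /= norm
    ang = np.radians(ANGLE_CA_C_N)
    ideal = c + BOND_C_N * (np.cos(ang) * u + np.sin(ang) * w_perp)
    return float(np.linalg.norm(n_act - ideal))


def total_chainbreak(pose: Pose, tree: FoldTree) -> float:
    """Sum of squared chainbreak deviations over the tree's cutpoints."""
    return sum(chainbreak_deviation(pose, cp) ** 2 for cp in tree.cutpoints)
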