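"""Programmatic toy antibody-antigen complexes for testing and demos.

Chains are poly-alanine/glycine peptides with idealized bond geometry (plus a
few lysine-like long side chains so packing has something to optimize),
assembled so that the three-chain system exercises every code path: helical
"framework" segments interleaved with designated CDR loop stretches on the
light and heavy chains, and a small helical antigen slid into contact with
the heavy-chain CDR region so the native complex has at least five
cross-partner residue contacts at the 5 A criterion.  Realistic antibody
geometry is explicitly not the goal.

Everything here is a pure function of (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .antibody import ParatopeMap, load_loop_definitions
from .evaluation import native_contacts
from .geometry import (
    ANGLE_C_N_CA, ANGLE_CA_C_N, ANGLE_CA_C_O, ANGLE_N_CA_C,
    BOND_C_N, BOND_C_O, BOND_CA_C, BOND_N_CA,
    normalize, place_atom, random_unit_vector, rotation_about_axis,
)
from .kinematics import build_loop_foldtree
from .structure import Atom, Pose, Residue, _ideal_sidechain

logger = logging.getLogger("snugdock")

HELIX = (-57.0, -47.0)
LOOP_TORSIONS = [(-70.0, 150.0), (-100.0, 60.0), (-80.0, 120.0)]


@dataclass
class FixtureSpec:
    """Layout of the toy complex.

    Chain layouts alternate framework and loop segments; H3 length defaults
    inside the 7-11 residue range typical of the benchmark systems the
    protocol targets.  Total size stays desk-scale (<= 60 residues).
    """

    loop_lengths: dict = field(default_factory=lambda: {
        "L1": 3, "L2": 3, "L3": 4, "H1": 3, "H2": 4, "H3": 8})
    framework_lengths: tuple = (3, 2, 2, 3)
    n_antigen: int = 8
    homology_error: float = 2.0     # target per-loop backbone rmsd, A
    vlvh_error_deg: float = 3.0     # V_L-V_H jump rotation in the mimic
    vlvh_error_trans: float = 0.5   # and translation, A
    ensemble_size: int = 5
    min_contacts: int = 5
    seed: int = 0

    def __post_init__(self):
        h3 = self.loop_lengths["H3"]
        if not 7 <= h3 <= 11:
            raise ValueError("H3 length must be in [7, 11]")
        total = (2 * sum(self.framework_lengths)
                 + sum(self.loop_lengths.values()) + self.n_antigen)
        if total > 60:
            raise ValueError(f"fixture too large ({total} residues > 60)")


# ---- peptide construction ---------------------------------------------


def build_peptide(torsions, names) -> list[Residue]:
    """Idealized-geometry peptide from per-residue (phi, psi) pairs; omega is
    trans throughout.  phi of the first residue is unused."""
    residues = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(ANGLE_N_CA_C)
    c = ca + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i, (name, (phi, psi)) in enumerate(zip(names, torsions)):
        if i > 0:
            prev = residues[-1]
            n = place_atom(prev.atom("N").coord, prev.atom("CA").coord,
                           prev.atom("C").coord, BOND_C_N, ANGLE_CA_C_N,
                           torsions[i - 1][1])
            ca = place_atom(prev.atom("CA").coord, prev.atom("C").coord, n,
                            BOND_N_CA, ANGLE_C_N_CA, 180.0)
            c = place_atom(prev.atom("C").coord, n, ca,
                           BOND_CA_C, ANGLE_N_CA_C, phi)
        o = place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        res = Residue(i + 1, name, [Atom.make("N", n), Atom.make("CA", ca),
                                    Atom.make("C", c), Atom.make("O", o)])
        res.atoms.extend(_ideal_sidechain(res))
        residues.append(res)
    return residues


def _chain_layout(spec: FixtureSpec, loop_names):
    """(torsions, residue names, loop ranges) for one antibody chain."""
    fw = spec.framework_lengths
    torsions, names = [], []
    ranges = {}
    pos = 0

    def add_framework(k, length):
        nonlocal pos
        for j in range(length):
            torsions.append(HELIX)
            # one long side chain per framework segment for packing tests
            names.append("LYS" if j == 0 and k > 0 else "ALA")
            pos += 1

    add_framework(0, fw[0])
    for k, loop_name in enumerate(loop_names):
        length = spec.loop_lengths[loop_name]
        start = pos + 1
        for j in range(length):
            torsions.append(LOOP_TORSIONS[j % len(LOOP_TORSIONS)])
            names.append("GLY" if j == length // 2 else "ALA")
            pos += 1
        ranges[loop_name] = (start, pos)
        add_framework(k + 1, fw[k + 1] if k + 1 < len(fw) else fw[-1])
    return torsions, names, ranges


def make_toy_complex(spec: FixtureSpec | None = None):
    """Build the native toy complex.

    Returns (pose, paratope): a full-atom three-chain Pose (L light, H heavy,
    A antigen) and its validated ParatopeMap.
    """
    spec = spec or FixtureSpec()
    lt, ln, lranges = _chain_layout(spec, ("L1", "L2", "L3"))
    ht, hn, hranges = _chain_layout(spec, ("H1", "H2", "H3"))

    light = build_peptide(lt, ln)
    heavy = build_peptide(ht, hn)
    antigen = build_peptide([HELIX] * spec.n_antigen,
                            ["ALA"] * (spec.n_antigen - 1) + ["LYS"])

    pose = Pose({"L": light, "H": heavy, "A": antigen},
                {"L": "light", "H": "heavy", "A": "antigen"})

    # place the heavy chain beside the light chain at a ~4.5 A closest gap
    _separate(pose, ["H"], ["L"], direction=np.array([0.0, 0.0, 1.0]), gap=4.5)

    loops_cfg = {"loops": [
        {"name": n, "chain": "L", "start": a, "stop": b} for n, (a, b) in lranges.items()
    ] + [
        {"name": n, "chain": "H", "start": a, "stop": b} for n, (a, b) in hranges.items()
    ]}
    paratope = load_loop_definitions(loops_cfg, pose)

    # aim the antigen at the H3 region and slide it into contact
    h3 = paratope.loop("H3")
    h3_pts = np.array([pose.residue("H", i).atom("CA").coord for i in h3.residues()])
    ab_com = pose.center_of_mass(pose.antibody_chains)
    outward = normalize(h3_pts.mean(axis=0) - ab_com)
    ag_com = pose.center_of_mass(["A"])
    target = h3_pts.mean(axis=0) + 12.0 * outward
    pose.transform_chains(["A"], np.eye(3), target - ag_com)

    from .moves import slide_into_contact
    pose = slide_into_contact(pose, target_gap=0.5)

    # press closer until the native contact count is reached
    axis = normalize(pose.center_of_mass(["A"]) - ab_com)
    for _ in range(60):
        if len(native_contacts(pose)) >= spec.min_contacts:
            break
        pose.transform_chains(["A"], np.eye(3), -0.25 * axis)
    else:
        raise RuntimeError("could not reach the requested native contact count")

    # a native complex sits in a binding-energy minimum: settle the antigen
    # placement into the nearest local minimum of the score so the fixture
    # behaves like a bound state rather than a glancing encounter
    from .energetics import minimize
    from .kinematics import MoveMap, build_docking_foldtree
    tree = build_docking_foldtree(pose)
    for _ in range(20):  # settle until converged (fresh step sizes each round)
        from .energetics import score
        e0 = score(pose).total
        pose = minimize(pose, tree, MoveMap(jumps_free={"dock"}), max_iter=100)
        if e0 - score(pose).total < 0.5:
            break

    if len(native_contacts(pose)) < spec.min_contacts:
        raise RuntimeError("settled native lost its contact count")
    pose.validate()
    return pose, paratope


def _separate(pose: Pose, mobile, fixed, direction, gap: float):
    """Translate ``mobile`` chains along ``direction`` so the closest
    heavy-atom gap (surface to surface) to ``fixed`` equals ``gap``."""
    from .moves import _heavy

    direction = normalize(direction)
    fpts, fr = _heavy(pose, fixed)
    mpts, mr = _heavy(pose, mobile)

    def min_gap(t):
        d = np.linalg.norm((mpts + t * direction)[:, None, :] - fpts[None, :, :], axis=2)
        return float((d - mr[:, None] - fr[None, :]).min())

    lo, hi = 0.0, 1.0
    while min_gap(hi) < gap:
        lo, hi = hi, hi * 2.0
        if hi > 1e4:
            raise RuntimeError("separation failed")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_gap(mid) < gap:
            lo = mid
        else:
            hi = mid
    pose.transform_chains(mobile, np.eye(3), hi * direction)


# ---- homology-model mimic ---------------------------------------------


def _loop_rmsd_to_native(pose: Pose, native: Pose, paratope: ParatopeMap,
                         loop_name: str) -> float:
    """Global CDR rmsd: superpose the owning chain's framework, query the
    loop backbone."""
    from .evaluation import _segment_rmsd

    lp = paratope.loop(loop_name)
    light = native.chain_ids("light")
    fw = paratope.framework_light if lp.chain in light else paratope.framework_heavy
    return _segment_rmsd(
        pose, native,
        lambda c, i: c == lp.chain and i in fw,
        lambda c, i: c == lp.chain and lp.start <= i <= lp.stop)


def _perturb_loop(pose: Pose, paratope: ParatopeMap, loop_name: str,
                  sigma: float, seed: int) -> Pose:
    """Gaussian phi/psi noise on the loop followed by CCD re-closure."""
    from .moves import ccd_close

    lp = paratope.loop(loop_name)
    tree = build_loop_foldtree(pose, [lp], allow_vl_vh=False)
    rng = np.random.default_rng(seed)
    out = pose.copy()
    from .kinematics import perturb_backbone_torsion
    for number in lp.residues():
        for angle in ("phi", "psi"):
            perturb_backbone_torsion(out, tree, lp.chain, number, angle,
                                     float(rng.normal(0.0, sigma)))
    out, _ = ccd_close(out, tree, lp, max_sweeps=200, tol=0.1)
    return out


def make_homology_mimic(native: Pose, paratope: ParatopeMap,
                        spec: FixtureSpec | None = None):
    """Perturbed-antibody starting structure emulating homology-model error.

    Each CDR loop's torsions are noised and CCD-reclosed, with the noise
    magnitude bisected until the loop's backbone rmsd to native lands within
    +/-20% of ``spec.homology_error``; the V_L-V_H orientation is then
    perturbed by the configured jump magnitude.  Returns (pose, ensemble)
    where ensemble holds ``spec.ensemble_size`` independent draws.
    """
    spec = spec or FixtureSpec()

    def one_mimic(draw: int) -> Pose:
        out = native.copy()
        if spec.homology_error <= 0:
            return out
        lo_t, hi_t = 0.8 * spec.homology_error, 1.2 * spec.homology_error
        for li, loop_name in enumerate(paratope.loops):
            seed = spec.seed * 1000 + draw * 101 + li
            lo, hi = 0.0, 10.0
            best, best_err = out, np.inf
            # grow the bracket until the loop is perturbed past target
            for _ in range(8):
                trial = _perturb_loop(out, paratope, loop_name, hi, seed)
                if _loop_rmsd_to_native(trial, native, paratope, loop_name) >= hi_t:
                    break
                hi *= 2.0
            for _ in range(25):
                mid = 0.5 * (lo + hi)
                trial = _perturb_loop(out, paratope, loop_name, mid, seed)
                r = _loop_rmsd_to_native(trial, native, paratope, loop_name)
                err = abs(r - spec.homology_error)
                if err < best_err:
                    best, best_err = trial, err
                if lo_t <= r <= hi_t:
                    break
                if r < spec.homology_error:
                    lo = mid
                else:
                    hi = mid
            else:
                logger.warning("mimic loop %s: best-effort rmsd off target by %.2f A",
                               loop_name, best_err)
            out = best

        # V_L-V_H orientation error
        rng = np.random.default_rng(spec.seed * 1000 + draw * 101 + 99)
        from .kinematics import build_docking_foldtree, apply_jump
        tree = build_docking_foldtree(out)
        R = rotation_about_axis(random_unit_vector(rng), spec.vlvh_error_deg)
        t = spec.vlvh_error_trans * random_unit_vector(rng)
        apply_jump(out, tree, "vl_vh", R, t)
        return out

    mimic = one_mimic(0)
    ensemble = [one_mimic(d + 1) for d in range(spec.ensemble_size)]
    return mimic, ensemble


def make_decoy_cloud(native: Pose, n: int, magnitude: float, seed: int = 0,
                     rot_deg: float = 0.0) -> list[Pose]:
    """Rigid-body antigen perturbations of the native complex spanning ligand
    rmsd up to ``magnitude`` (pure translations by default, so the rmsd of
    each decoy equals its displacement)."""
    rng = np.random.default_rng(seed)
    decoys = []
    for _ in range(n):
        out = native.copy()
        t = magnitude * rng.random() * random_unit_vector(rng)
        R = np.eye(3)
        if rot_deg > 0:
            R = rotation_about_axis(random_unit_vector(rng),
                                    float(rng.normal(0.0, rot_deg)))
        com = out.center_of_mass(out.antigen_chains)
        out.transform_chains(out.antigen_chains, R, t + com - R @ com)
        decoys.append(out)
    return decoys
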