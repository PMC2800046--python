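"""Structural perturbation operators.

Starting-position generators (local spin/tilt/translate and global random
orientation), slide-into-contact, Gaussian rigid-body perturbations of either
jump, small/shear backbone torsion moves, analytic cyclic-coordinate-descent
(CCD) loop closure, composite loop relaxation, ensemble conformer swapping and
the weighted five-move selector used by the high-resolution stage.

Every operator is an isometry of some rigid body or a pure torsion change, so
bond lengths and angles are conserved, and every randomized operator is a pure
function of (pose, parameters, rng state).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .antibody import LoopDefinition, ParatopeMap
from .energetics import ScoreWeights, metropolis_accept, score
from .geometry import (
    kabsch_rotation,
    normalize,
    random_unit_vector,
    rotation_about_axis,
)
from .kinematics import (
    Cutpoint,
    FoldTree,
    apply_jump,
    chainbreak_deviation,
    perturb_backbone_torsion,
    rotate_torsion_branch,
)
from .structure import Pose

MOVE_NAMES = ("dock_rb", "vlvh_rb", "cdr_min", "h3_relax", "h2_relax")

#: printed selection probabilities of the five high-resolution moves
DEFAULT_MOVE_WEIGHTS = {
    "dock_rb": 0.40,
    "vlvh_rb": 0.40,
    "cdr_min": 0.10,
    "h3_relax": 0.05,
    "h2_relax": 0.05,
}


@dataclass(frozen=True)
class MoveSpec:
    name: str
    weight: float
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in MOVE_NAMES:
            raise ValueError(f"unknown move {self.name!r}")
        if self.weight < 0:
            raise ValueError("move weight must be >= 0")


def default_move_specs() -> list[MoveSpec]:
    return [MoveSpec(n, w) for n, w in DEFAULT_MOVE_WEIGHTS.items()]


@dataclass(frozen=True)
class PerturbParams:
    """Magnitudes for starting perturbations and rigid-body moves."""

    trans_sigma: float = 0.1   # high-res Gaussian translation, A
    rot_sigma: float = 3.0     # high-res Gaussian rotation, deg
    init_trans: float = 8.0    # local start translation sigma, A
    init_tilt: float = 8.0     # local start tilt sigma, deg
    lowres_trans: float = 0.7  # low-res antibody perturbation, A
    lowres_rot: float = 5.0    # low-res antibody perturbation, deg

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


# ---- starting positions ------------------------------------------------


def _centers_axis(pose: Pose):
    ab = pose.center_of_mass(pose.antibody_chains)
    ag = pose.center_of_mass(pose.antigen_chains)
    axis = ag - ab
    if np.linalg.norm(axis) < 1e-6:
        raise ValueError("antibody and antigen centers of mass coincide")
    return ab, ag, normalize(axis)


def local_perturb_start(pose: Pose, params: PerturbParams,
                        rng: np.random.Generator) -> Pose:
    """Local start: spin the antigen uniformly 0-360 deg about the axis
    joining the two centers of mass, tilt it off-axis by a Gaussian draw
    (sigma ``init_tilt``) and translate along the axis by a Gaussian draw
    (sigma ``init_trans``); the antibody never moves."""
    out = pose.copy()
    ab, ag, axis = _centers_axis(out)
    spin = rng.uniform(0.0, 360.0)
    R = rotation_about_axis(axis, spin)
    out.transform_chains(out.antigen_chains, R, ab - R @ ab)
    # tilt: swing about a random axis perpendicular to the centers axis
    tilt = rng.normal(0.0, params.init_tilt)
    perp = normalize(np.cross(axis, random_unit_vector(rng)))
    R = rotation_about_axis(perp, tilt)
    out.transform_chains(out.antigen_chains, R, ab - R @ ab)
    shift = rng.normal(0.0, params.init_trans)
    out.transform_chains(out.antigen_chains, np.eye(3), shift * axis)
    return out


def global_randomize_start(pose: Pose, paratope: ParatopeMap,
                           rng: np.random.Generator,
                           reorient_sigma: float = 10.0) -> Pose:
    """Global start: draw the antigen orientation uniformly on rotations
    (about its own center of mass), then rotate the whole antibody so its
    paratope points at the antigen center, plus a small Gaussian perturbation
    so the paratope stays only generally directed at the antigen."""
    out = pose.copy()
    ag_com = out.center_of_mass(out.antigen_chains)
    R = Rotation.random(random_state=rng).as_matrix()
    out.transform_chains(out.antigen_chains, R, ag_com - R @ ag_com)

    ab_com = out.center_of_mass(out.antibody_chains)
    pts = []
    for chain, number in paratope.paratope:
        res = out.residue(chain, number)
        if res.has_atom("CA"):
            pts.append(res.atom("CA").coord)
    par_axis = normalize(np.mean(pts, axis=0) - ab_com)
    target_axis = normalize(ag_com - ab_com)
    align, _ = Rotation.align_vectors(target_axis[None, :], par_axis[None, :])
    R = align.as_matrix()
    wobble = rotation_about_axis(random_unit_vector(rng),
                                 rng.normal(0.0, reorient_sigma))
    R = wobble @ R
    out.transform_chains(out.antibody_chains, R, ab_com - R @ ab_com)
    return out


def slide_into_contact(pose: Pose, target_gap: float = 1.0,
                       tol: float = 1e-3, max_iter: int = 200) -> Pose:
    """Translate the antigen along the centers axis until the smallest
    cross-partner atomic gap (d - r_i - r_j) first reaches ``target_gap``
    from outside (glancing contact within 1 A of van der Waals distance);
    overlapped inputs are pulled apart until the same criterion holds."""
    out = pose.copy()
    ab_chains = out.antibody_chains
    ag_chains = out.antigen_chains

    ab_pts, ab_r = _heavy(out, ab_chains)
    tree_ab = cKDTree(ab_pts)
    rmax = float(ab_r.max())

    def min_gap(offset: np.ndarray) -> float:
        pts = ag0 + offset
        d, idx = tree_ab.query(pts, k=1)
        # refine: query returns nearest center; gap needs radii, so check a
        # neighborhood around the nearest few candidates
        cand = tree_ab.query_ball_point(pts, r=d.max() + 2 * rmax + 1.0)
        best = np.inf
        for ia, hits in enumerate(cand):
            if not hits:
                continue
            dd = np.linalg.norm(ab_pts[hits] - pts[ia], axis=1)
            gaps = dd - ab_r[hits] - ag_r[ia]
            best = min(best, gaps.min())
        return best

    ag0, ag_r = _heavy(out, ag_chains)
    _, _, axis = _centers_axis(out)

    # bracket: t < 0 moves the antigen toward the antibody
    g0 = min_gap(np.zeros(3))
    lo, hi = None, None
    if g0 > target_gap:  # outside: approach
        t_out = 0.0
        t_in = -2.0
        for _ in range(max_iter):
            if min_gap(t_in * axis) <= target_gap:
                lo, hi = t_in, t_out
                break
            t_out, t_in = t_in, t_in - 2.0
    else:  # touching/overlapped: retreat
        t_in = 0.0
        t_out = 2.0
        for _ in range(max_iter):
            if min_gap(t_out * axis) > target_gap:
                lo, hi = t_in, t_out
                break
            t_in, t_out = t_out, t_out + 2.0
    if lo is None:
        raise RuntimeError("slide_into_contact: could not bracket a contact")

    # bisect for the outermost offset with gap <= target_gap
    for _ in range(max_iter):
        if hi - lo < tol:
            break
        mid = 0.5 * (lo + hi)
        if min_gap(mid * axis) <= target_gap:
            lo = mid
        else:
            hi = mid
    out.transform_chains(ag_chains, np.eye(3), lo * axis)
    return out


def _heavy(pose: Pose, chains):
    pts, radii = [], []
    for _, _, a in pose.iter_atoms(chains):
        if not a.is_hydrogen:
            pts.append(a.coord)
            radii.append(a.vdw_radius)
    return np.array(pts), np.array(radii)


# ---- rigid body and backbone moves ------------------------------------


def rigid_body_perturb(pose: Pose, tree: FoldTree, jump_key,
                       trans_sigma: float, rot_sigma: float,
                       rng: np.random.Generator) -> Pose:
    """Gaussian translation (sigma per axis) plus Gaussian rotation about a
    uniformly random axis, applied to the jump's downstream body about its
    center of mass."""
    out = pose.copy()
    t = rng.normal(0.0, trans_sigma, size=3) if trans_sigma > 0 else np.zeros(3)
    angle = rng.normal(0.0, rot_sigma) if rot_sigma > 0 else 0.0
    axis = random_unit_vector(rng)
    R = rotation_about_axis(axis, angle) if angle != 0.0 else np.eye(3)
    apply_jump(out, tree, jump_key, R, t)
    return out


def small_move(pose: Pose, tree: FoldTree, loop: LoopDefinition,
               max_angle: float, rng: np.random.Generator) -> Pose:
    """Perturb one random loop residue's phi or psi uniformly in
    +/- max_angle; propagation stops at the loop cutpoint and stems."""
    out = pose.copy()
    number = int(rng.integers(loop.start, loop.stop + 1))
    angle_name = "phi" if rng.random() < 0.5 else "psi"
    delta = rng.uniform(-max_angle, max_angle)
    if delta != 0.0:
        perturb_backbone_torsion(out, tree, loop.chain, number, angle_name, delta)
    return out


def shear_move(pose: Pose, tree: FoldTree, loop: LoopDefinition,
               max_angle: float, rng: np.random.Generator) -> Pose:
    """Compensating pair: phi of residue i by +delta and psi of residue i-1
    by -delta, limiting downstream lever-arm propagation."""
    out = pose.copy()
    number = int(rng.integers(loop.start + 1, loop.stop + 1))
    delta = rng.uniform(-max_angle, max_angle)
    if delta != 0.0:
        perturb_backbone_torsion(out, tree, loop.chain, number, "phi", delta)
        perturb_backbone_torsion(out, tree, loop.chain, number - 1, "psi", -delta)
    return out


# ---- CCD loop closure --------------------------------------------------


def _ccd_targets(pose: Pose, loop: LoopDefinition):
    """Fixed target positions: actual N, CA, C of the residue after the cut
    (owned by the backward-built half anchored at the stop stem)."""
    nxt = pose.residue(loop.chain, loop.cutpoint + 1)
    return np.array([nxt.atom(x).coord for x in ("N", "CA", "C")])


def _ccd_virtual(pose: Pose, loop: LoopDefinition, psi_v: float, phi_v: float):
    """Moving anchors: ideal forward continuation N, CA, C built from the cut
    residue with ideal geometry, omega fixed trans; the two continuation
    torsions are free closure DOFs."""
    from .geometry import (
        ANGLE_C_N_CA, ANGLE_CA_C_N, ANGLE_N_CA_C,
        BOND_C_N, BOND_CA_C, BOND_N_CA, place_atom,
    )
    res = pose.residue(loop.chain, loop.cutpoint)
    n, ca, c = (res.atom(x).coord for x in ("N", "CA", "C"))
    n_v = place_atom(n, ca, c, BOND_C_N, ANGLE_CA_C_N, psi_v)
    ca_v = place_atom(ca, c, n_v, BOND_N_CA, ANGLE_C_N_CA, 180.0)
    c_v = place_atom(c, n_v, ca_v, BOND_CA_C, ANGLE_N_CA_C, phi_v)
    return np.array([n_v, ca_v, c_v])


def _ccd_objective(pose: Pose, loop: LoopDefinition, psi_v, phi_v) -> float:
    m = _ccd_virtual(pose, loop, psi_v, phi_v)
    f = _ccd_targets(pose, loop)
    return float(np.sum((m - f) ** 2))


def _optimal_ccd_angle(moving: np.ndarray, fixed: np.ndarray,
                       origin: np.ndarray, axis: np.ndarray) -> float:
    """Closed-form rotation angle about (origin, axis) minimizing
    sum |R(theta) m_k - f_k|^2 (the classic CCD update)."""
    u = normalize(axis)
    a = b = 0.0
    for m, f in zip(moving, fixed):
        r = m - origin
        s = r - np.dot(r, u) * u
        cvec = (f - origin) - np.dot(f - origin, u) * u
        a += np.dot(cvec, s)
        b += np.dot(cvec, np.cross(u, s))
    if abs(a) < 1e-14 and abs(b) < 1e-14:
        return 0.0
    return float(np.degrees(np.arctan2(b, a)))


def ccd_close(pose: Pose, tree: FoldTree, loop: LoopDefinition,
              max_sweeps: int = 100, tol: float = 0.15,
              rng: np.random.Generator | None = None):
    """Cyclic coordinate descent closure of the loop's cutpoint.

    Sweeps over the loop's phi/psi torsions (both halves) plus the two
    virtual continuation torsions; each update is the analytic single-axis
    minimizer of the squared anchor mismatch, so the objective is monotone
    non-increasing per update.  Returns (pose, info) where info reports
    convergence and the final chainbreak deviation.
    """
    out = pose.copy()
    cp = Cutpoint(loop.chain, loop.cutpoint)
    cut_pos = out.residue_index(loop.chain, loop.cutpoint)
    # initialize virtual torsions from the current (broken) geometry
    psi_v = out.backbone_torsion(loop.chain, cut_pos, "psi")
    nxt_pos = cut_pos + 1
    phi_v = out.backbone_torsion(loop.chain, nxt_pos, "phi")

    dev = chainbreak_deviation(out, cp)
    sweeps = 0
    for sweep in range(max_sweeps):
        if dev <= tol:
            break
        sweeps = sweep + 1
        for number in range(loop.start, loop.stop + 1):
            for angle_name in ("phi", "psi"):
                if number == loop.cutpoint + 1 and angle_name == "phi":
                    continue  # backward phi of the first post-cut residue moves nothing
                res = out.residue(loop.chain, number)
                n, ca, c = (res.atom(x).coord for x in ("N", "CA", "C"))
                if angle_name == "phi":
                    origin, axis = n, ca - n
                else:
                    origin, axis = ca, c - ca
                targets = _ccd_targets(out, loop)
                virtual = _ccd_virtual(out, loop, psi_v, phi_v)
                if number <= loop.cutpoint:
                    # branch carries the virtual anchors toward the fixed targets
                    theta = _optimal_ccd_angle(virtual, targets, origin, axis)
                elif number == loop.cutpoint + 1:
                    # psi here moves only the actual N anchor
                    theta = _optimal_ccd_angle(targets[:1], virtual[:1], origin, axis)
                else:
                    # branch carries the actual anchors toward the virtual ones
                    theta = _optimal_ccd_angle(targets, virtual, origin, axis)
                if abs(theta) > 1e-10:
                    rotate_torsion_branch(out, tree, loop.chain, number,
                                          angle_name, theta)
        # virtual continuation torsions (move the virtual anchors only)
        res = out.residue(loop.chain, loop.cutpoint)
        virtual = _ccd_virtual(out, loop, psi_v, phi_v)
        targets = _ccd_targets(out, loop)
        origin, axis = res.atom("CA").coord, res.atom("C").coord - res.atom("CA").coord
        psi_v += _optimal_ccd_angle(virtual, targets, origin, axis)
        virtual = _ccd_virtual(out, loop, psi_v, phi_v)
        origin, axis = virtual[0], virtual[1] - virtual[0]
        phi_v += _optimal_ccd_angle(virtual[2:], targets[2:], origin, axis)
        dev = chainbreak_deviation(out, cp)
    info = {"converged": dev <= tol, "sweeps": sweeps, "deviation": dev}
    return out, info


def loop_relax(pose: Pose, tree: FoldTree, loop: LoopDefinition,
               rng: np.random.Generator, resolution: str | None = None,
               n_small: int = 5, n_shear: int = 5, max_angle: float | None = None,
               minimize_after: bool = False,
               weights: ScoreWeights | None = None,
               min_max_iter: int = 20):
    """Composite relaxation: small + shear torsion moves, CCD re-closure and
    (optionally, high resolution) torsion minimization of the loop.  The
    V_L-V_H jump stays frozen throughout via the loop fold tree."""
    resolution = resolution or pose.resolution
    if max_angle is None:
        max_angle = 6.0 if resolution == "centroid" else 3.0
    out = pose
    for _ in range(n_small):
        out = small_move(out, tree, loop, max_angle, rng)
    for _ in range(n_shear):
        out = shear_move(out, tree, loop, max_angle, rng)
    out, info = ccd_close(out, tree, loop, rng=rng)
    if minimize_after:
        from .energetics import minimize
        from .kinematics import MoveMap
        mm = MoveMap(backbone_free={(loop.chain, i) for i in loop.residues()})
        out = minimize(out, tree, mm, weights, max_iter=min_max_iter)
    return out, info


# ---- ensemble swap and move selection ----------------------------------


def conformer_swap(pose: Pose, ensemble: list[Pose], kT: float,
                   rng: np.random.Generator,
                   weights: ScoreWeights | None = None,
                   tree: FoldTree | None = None) -> Pose:
    """Monte Carlo backbone swap: superpose a random ensemble member's
    antibody onto the current antibody placement, replace the antibody
    coordinates, and accept or reject by the Metropolis criterion on the
    (low-resolution) score.  The antigen never moves."""
    if not ensemble:
        raise ValueError("ensemble must contain at least one pose")
    weights = weights or ScoreWeights()
    pick = ensemble[int(rng.integers(len(ensemble)))]
    ab = pose.antibody_chains
    if set(pick.antibody_chains) != set(ab):
        raise ValueError("ensemble member chain layout mismatch")

    cand = pose.copy()
    src = pick.backbone_coords(ab)
    dst = pose.backbone_coords(ab)
    if src.shape != dst.shape:
        raise ValueError("ensemble member residue layout mismatch")
    R, t = kabsch_rotation(src, dst)
    for cid in ab:
        if len(pick.chains[cid]) != len(pose.chains[cid]):
            raise ValueError("ensemble member residue layout mismatch")
        for r_new, r_src in zip(cand.chains[cid], pick.chains[cid]):
            if r_new.name != r_src.name:
                raise ValueError("ensemble member residue identity mismatch")
            r_new.atoms = [type(a)(a.name, a.element, R @ a.coord + t,
                                   a.is_backbone, a.is_hydrogen, a.vdw_radius)
                           for a in r_src.atoms]
    e_old = score(pose, weights, tree).total
    e_new = score(cand, weights, tree).total
    if metropolis_accept(e_new - e_old, kT, rng):
        return cand
    return pose.copy()


def select_move(specs: list[MoveSpec], rng: np.random.Generator) -> MoveSpec:
    """Categorical draw over the move set by weight."""
    w = np.array([s.weight for s in specs], dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("all move weights are zero")
    idx = int(rng.choice(len(specs), p=w / total))
    return specs[idx]
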