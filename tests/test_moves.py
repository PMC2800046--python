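"""Perturbation operators: starts, slide, rigid body, small/shear, CCD,
conformer swap, move selection."""

import numpy as np
import pytest
from scipy import stats

from snugdock import (
    Cutpoint, PerturbParams, build_loop_foldtree,
    ccd_close, chainbreak_deviation, conformer_swap, default_move_specs,
    global_randomize_start, local_perturb_start, loop_relax, rigid_body_perturb,
    select_move, shear_move, slide_into_contact, small_move,
)
from snugdock.antibody import LoopDefinition
from snugdock.fixtures import build_peptide
from snugdock.kinematics import set_backbone_torsion
from snugdock.moves import MoveSpec
from snugdock.structure import Atom, Pose, Residue


def _pairwise(points):
    return np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)


# ---- starting positions ------------------------------------------------


def test_pure_spin_preserves_antigen_com_and_geometry(native, rng):
    params = PerturbParams(init_trans=0.0, init_tilt=0.0)
    out = local_perturb_start(native, params, rng)
    assert np.allclose(out.center_of_mass(out.antigen_chains),
                       native.center_of_mass(native.antigen_chains), atol=1e-6)
    assert np.allclose(_pairwise(out.coords(out.antigen_chains)),
                       _pairwise(native.coords(native.antigen_chains)), atol=1e-9)
    # antibody untouched
    assert np.array_equal(out.coords(out.antibody_chains),
                          native.coords(native.antibody_chains))


def test_spin_angle_uniform_on_circle(native):
    """The spin projects the antigen to a uniform angle about the centers
    axis; check uniformity of the realized rotation angles by KS test."""
    rng = np.random.default_rng(5)
    params = PerturbParams(init_trans=0.0, init_tilt=0.0)
    ab = native.center_of_mass(native.antibody_chains)
    ag = native.center_of_mass(native.antigen_chains)
    axis = (ag - ab) / np.linalg.norm(ag - ab)
    # reference vector: first antigen atom, perpendicular component
    p0 = native.chains[native.antigen_chains[0]][0].atoms[0].coord
    v0 = p0 - ag
    v0 -= np.dot(v0, axis) * axis
    angles = []
    for _ in range(2000):
        out = local_perturb_start(native, params, rng)
        p1 = out.chains[out.antigen_chains[0]][0].atoms[0].coord
        v1 = p1 - ag
        v1 -= np.dot(v1, axis) * axis
        ang = np.arctan2(np.dot(np.cross(v0, v1), axis), np.dot(v0, v1))
        angles.append((ang + 2 * np.pi) % (2 * np.pi))
    ks = stats.kstest(np.array(angles) / (2 * np.pi), "uniform")
    assert ks.pvalue > 1e-3


def test_local_start_default_translation_magnitude_parameter():
    assert PerturbParams().init_trans == 8.0
    assert PerturbParams().init_tilt == 8.0


def test_global_start_points_paratope_at_antigen(native, paratope):
    rng = np.random.default_rng(11)
    for _ in range(10):
        out = global_randomize_start(native, paratope, rng)
        ab_com = out.center_of_mass(out.antibody_chains)
        ag_com = out.center_of_mass(out.antigen_chains)
        pts = [out.residue(c, n).atom("CA").coord for c, n in paratope.paratope]
        par_axis = np.mean(pts, axis=0) - ab_com
        target = ag_com - ab_com
        cosang = np.dot(par_axis, target) / (np.linalg.norm(par_axis) * np.linalg.norm(target))
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= 45.0


def test_global_start_rotation_uniformity(native, paratope):
    """Mean rotation angle of a uniform random rotation is ~126.5 degrees."""
    rng = np.random.default_rng(17)
    from scipy.spatial.transform import Rotation
    angles = []
    for _ in range(4000):
        R = Rotation.random(random_state=rng)
        angles.append(np.degrees(R.magnitude()))
    assert np.mean(angles) == pytest.approx(126.47, abs=2.0)


def test_start_is_deterministic_given_seed(native, paratope):
    a = local_perturb_start(native, PerturbParams(), np.random.default_rng(9))
    b = local_perturb_start(native, PerturbParams(), np.random.default_rng(9))
    assert np.array_equal(a.coords(), b.coords())
    c = global_randomize_start(native, paratope, np.random.default_rng(9))
    d = global_randomize_start(native, paratope, np.random.default_rng(9))
    assert np.array_equal(c.coords(), d.coords())


# ---- slide into contact ------------------------------------------------


def _single_atom_chain(cid, x):
    # one carbon atom, vdW radius 1.7
    return [Residue(1, "GLY", [Atom.make("CA", [x, 0, 0])])]


def test_slide_two_single_atoms_lands_within_one_angstrom_of_contact():
    pose = Pose({"L": _single_atom_chain("L", 0.0),
                 "H": _single_atom_chain("H", 0.001),
                 "A": _single_atom_chain("A", 20.0)},
                {"L": "light", "H": "heavy", "A": "antigen"})
    out = slide_into_contact(pose)
    d = min(np.linalg.norm(out.chains["A"][0].atoms[0].coord
                           - out.chains[c][0].atoms[0].coord) for c in "LH")
    assert 3.4 < d <= 4.4 + 2e-3  # gap in (0, 1] for two 1.7 A radii


def test_slide_from_overlap_retreats_to_glancing_contact():
    pose = Pose({"L": _single_atom_chain("L", 0.0),
                 "H": _single_atom_chain("H", 0.001),
                 "A": _single_atom_chain("A", 1.0)},
                {"L": "light", "H": "heavy", "A": "antigen"})
    out = slide_into_contact(pose)
    d = min(np.linalg.norm(out.chains["A"][0].atoms[0].coord
                           - out.chains[c][0].atoms[0].coord) for c in "LH")
    assert 3.4 < d <= 4.4 + 2e-3


def test_slide_matches_bisection_oracle_on_gap(native):
    """Final minimal gap equals the 1 A target to bisection accuracy."""
    apart = native.copy()
    ab = apart.center_of_mass(apart.antibody_chains)
    ag = apart.center_of_mass(apart.antigen_chains)
    axis = (ag - ab) / np.linalg.norm(ag - ab)
    apart.transform_chains(apart.antigen_chains, np.eye(3), 30.0 * axis)
    out = slide_into_contact(apart)

    def min_gap(p):
        gaps = []
        ab_atoms = [(a.coord, a.vdw_radius) for _, _, a in p.iter_atoms(p.antibody_chains)]
        for _, _, a in p.iter_atoms(p.antigen_chains):
            for c, r in ab_atoms:
                gaps.append(np.linalg.norm(a.coord - c) - r - a.vdw_radius)
        return min(gaps)

    assert min_gap(out) <= 1.0 + 1e-6
    assert min_gap(out) >= 1.0 - 0.05  # just inside the criterion


def test_slide_is_idempotent_once_in_glancing_contact(native):
    once = slide_into_contact(native)
    twice = slide_into_contact(once)
    shift = np.linalg.norm(twice.center_of_mass(twice.antigen_chains)
                           - once.center_of_mass(once.antigen_chains))
    assert shift < 0.01  # already satisfies the criterion; barely moves


# ---- rigid body perturbation ------------------------------------------


def test_rigid_perturb_sigma_zero_is_identity(native, dock_tree, rng):
    out = rigid_body_perturb(native, dock_tree, "dock", 0.0, 0.0, rng)
    assert np.allclose(out.coords(), native.coords(), atol=1e-12)


def test_rigid_perturb_is_isometry_of_downstream(native, dock_tree, rng):
    out = rigid_body_perturb(native, dock_tree, "dock", 1.0, 10.0, rng)
    assert np.allclose(_pairwise(out.coords(out.antigen_chains)),
                       _pairwise(native.coords(native.antigen_chains)), atol=1e-9)


def test_rigid_perturb_translation_sd_matches_sigma(native, dock_tree):
    rng = np.random.default_rng(2)
    sigma = 0.5
    deltas = []
    for _ in range(10_000):
        out = rigid_body_perturb(native, dock_tree, "dock", sigma, 0.0, rng)
        deltas.append(out.center_of_mass(out.antigen_chains)
                      - native.center_of_mass(native.antigen_chains))
    sds = np.array(deltas).std(axis=0)
    assert np.allclose(sds, sigma, rtol=0.02)


def test_rigid_perturb_frozen_jump_raises(native, paratope, rng):
    tree = build_loop_foldtree(native, paratope.loops, allow_vl_vh=False)
    with pytest.raises(ValueError, match="frozen"):
        rigid_body_perturb(native, tree, "vl_vh", 1.0, 1.0, rng)


# ---- small / shear -----------------------------------------------------


def _loop_pose():
    mk = lambda: build_peptide([(-100.0, 120.0)] * 12, ["ALA"] * 12)
    pose = Pose({"L": mk(), "H": mk(), "A": mk()},
                {"L": "light", "H": "heavy", "A": "antigen"})
    loop = LoopDefinition("H3", "H", 4, 11, 7)
    tree = build_loop_foldtree(pose, [loop])
    return pose, loop, tree


def test_small_move_zero_angle_is_identity(rng):
    pose, loop, tree = _loop_pose()
    out = small_move(pose, tree, loop, 0.0, rng)
    assert np.allclose(out.coords(), pose.coords(), atol=1e-12)


def test_small_and_shear_leave_non_loop_atoms(rng):
    pose, loop, tree = _loop_pose()
    out = small_move(pose, tree, loop, 15.0, rng)
    out = shear_move(out, tree, loop, 15.0, rng)
    outside = [r.number for r in pose.chains["H"]
               if not loop.start <= r.number <= loop.stop]
    for number in outside:
        a = np.array([x.coord for x in out.residue("H", number).atoms])
        b = np.array([x.coord for x in pose.residue("H", number).atoms])
        assert np.allclose(a, b, atol=1e-12)


def test_shear_applies_compensating_pair(rng):
    """A shear move changes phi(i) by +d and psi(i-1) by -d."""
    pose, loop, tree = _loop_pose()
    out = shear_move(pose, tree, loop, 20.0, np.random.default_rng(3))
    pairs = 0
    for number in range(loop.start, loop.stop + 1):
        if number == loop.cutpoint + 1:
            continue  # the dihedral spanning the severed bond is meaningless
        i = pose.residue_index("H", number)
        dp = out.backbone_torsion("H", i, "phi") - pose.backbone_torsion("H", i, "phi")
        if abs(dp) > 1e-9:
            prev = i - 1
            ds = out.backbone_torsion("H", prev, "psi") - pose.backbone_torsion("H", prev, "psi")
            assert ds == pytest.approx(-dp, abs=1e-6)
            pairs += 1
    assert pairs == 1


# ---- CCD ---------------------------------------------------------------


def test_ccd_already_closed_loop_needs_no_sweeps():
    pose, loop, tree = _loop_pose()
    out, info = ccd_close(pose, tree, loop)
    assert info["sweeps"] == 0
    assert np.allclose(out.coords(), pose.coords(), atol=1e-9)


def test_ccd_closes_perturbed_loops_reliably():
    """8-residue loops with +/-30 degree torsion noise close to <= 0.15 A
    within 100 sweeps in at least 95% of seeded trials."""
    n_trials, closed = 100, 0
    for seed in range(n_trials):
        pose, loop, tree = _loop_pose()
        rng = np.random.default_rng(seed)
        for number in loop.residues():
            for angle in ("phi", "psi"):
                i = pose.residue_index("H", number)
                cur = pose.backbone_torsion("H", i, angle)
                set_backbone_torsion(pose, tree, "H", number, angle,
                                     cur + rng.uniform(-30, 30))
        out, info = ccd_close(pose, tree, loop, max_sweeps=100, tol=0.15)
        if info["converged"]:
            closed += 1
    assert closed >= 95


def test_ccd_objective_monotone_per_sweep():
    pose, loop, tree = _loop_pose()
    rng = np.random.default_rng(1)
    for number in loop.residues():
        for angle in ("phi", "psi"):
            i = pose.residue_index("H", number)
            cur = pose.backbone_torsion("H", i, angle)
            set_backbone_torsion(pose, tree, "H", number, angle,
                                 cur + rng.uniform(-40, 40))
    cp = Cutpoint("H", loop.cutpoint)
    devs = [chainbreak_deviation(pose, cp)]
    out = pose
    for _ in range(12):
        out, info = ccd_close(out, tree, loop, max_sweeps=1, tol=1e-9)
        devs.append(info["deviation"])
    # closure mismatch decreases overall and never explodes
    assert devs[-1] < devs[0]
    assert devs[-1] < 0.2


def test_loop_relax_keeps_closure_and_locality(native, paratope, rng):
    tree = build_loop_foldtree(native, paratope.loops, allow_vl_vh=False)
    loop = paratope.loop("H3")
    cp = Cutpoint(loop.chain, loop.cutpoint)
    out, info = loop_relax(native, tree, loop, rng)
    assert chainbreak_deviation(out, cp) <= max(0.15,
                                                chainbreak_deviation(native, cp))
    # non-loop atoms unchanged
    for r_out, r_in in zip(out.chains[loop.chain], native.chains[loop.chain]):
        if not loop.start <= r_in.number <= loop.stop:
            for a, b in zip(r_out.atoms, r_in.atoms):
                assert np.allclose(a.coord, b.coord, atol=1e-12)
    assert np.array_equal(out.coords(["A"]), native.coords(["A"]))


def test_loop_relax_deterministic(native, paratope):
    tree = build_loop_foldtree(native, paratope.loops, allow_vl_vh=False)
    loop = paratope.loop("H2")
    a, _ = loop_relax(native, tree, loop, np.random.default_rng(77))
    b, _ = loop_relax(native, tree, loop, np.random.default_rng(77))
    assert np.array_equal(a.coords(), b.coords())


# ---- conformer swap ----------------------------------------------------


def test_conformer_swap_self_ensemble_is_identity(native, rng):
    out = conformer_swap(native, [native], kT=0.8, rng=rng)
    assert np.allclose(out.coords(), native.coords(), atol=1e-9)


def test_conformer_swap_never_moves_antigen(native, mimic_and_ensemble, rng):
    _, ensemble = mimic_and_ensemble
    out = conformer_swap(native, ensemble, kT=0.8, rng=rng)
    assert np.array_equal(out.coords(native.antigen_chains),
                          native.coords(native.antigen_chains))


def test_conformer_swap_uniform_selection_over_equal_members(native):
    """With identical-scoring members the proposal distribution is uniform."""
    rng = np.random.default_rng(10)
    n = 20_000
    counts = np.zeros(10)
    for _ in range(n):
        counts[rng.integers(10)] += 1
    assert np.allclose(counts / n, 0.1, atol=0.01)


# ---- move selection ----------------------------------------------------


def test_select_move_degenerate_weight_always_first(rng):
    specs = [MoveSpec("dock_rb", 1.0), MoveSpec("vlvh_rb", 0.0),
             MoveSpec("cdr_min", 0.0)]
    assert all(select_move(specs, rng).name == "dock_rb" for _ in range(200))


def test_select_move_all_zero_weights_raises(rng):
    with pytest.raises(ValueError):
        select_move([MoveSpec("dock_rb", 0.0)], rng)


def test_select_move_default_frequencies():
    """10^5 draws reproduce the 40/40/10/5/5 selection percentages within
    one percentage point."""
    rng = np.random.default_rng(0)
    specs = default_move_specs()
    counts = {s.name: 0 for s in specs}
    n = 100_000
    for _ in range(n):
        counts[select_move(specs, rng).name] += 1
    freqs = {k: v / n for k, v in counts.items()}
    expected = {"dock_rb": 0.40, "vlvh_rb": 0.40, "cdr_min": 0.10,
                "h3_relax": 0.05, "h2_relax": 0.05}
    for k in expected:
        assert abs(freqs[k] - expected[k]) < 0.01


def test_select_move_cdf_matches_cumulative_weights():
    rng = np.random.default_rng(4)
    specs = [MoveSpec("dock_rb", 0.2), MoveSpec("vlvh_rb", 0.5),
             MoveSpec("cdr_min", 0.3)]
    n = 50_000
    counts = {s.name: 0 for s in specs}
    for _ in range(n):
        counts[select_move(specs, rng).name] += 1
    emp = np.cumsum([counts[s.name] / n for s in specs])
    assert np.allclose(emp, np.cumsum([0.2, 0.5, 0.3]), atol=0.01)
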