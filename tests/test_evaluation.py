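"""Docking metrics, CAPRI classification, funnel and diversity."""

import numpy as np
import pytest

from snugdock import (
    capri_rate, detect_funnel, diversity_stats, fnat, interface_rmsd,
    ligand_rmsd, make_decoy_cloud, native_contacts,
)
from snugdock.geometry import rotation_about_axis

from conftest import brute_force_rmsd_after_superposition, kabsch_oracle


def test_self_metrics(native):
    assert ligand_rmsd(native, native) == pytest.approx(0.0, abs=1e-9)
    assert interface_rmsd(native, native) == pytest.approx(0.0, abs=1e-9)
    assert fnat(native, native) == 1.0


def test_ligand_rmsd_equals_pure_translation(native):
    moved = native.copy()
    moved.transform_chains(moved.antigen_chains, np.eye(3), np.array([3.0, 0, 0]))
    assert ligand_rmsd(moved, native) == pytest.approx(3.0, abs=1e-9)


def test_fnat_zero_when_separated(native):
    moved = native.copy()
    moved.transform_chains(moved.antigen_chains, np.eye(3), np.array([500.0, 0, 0]))
    assert fnat(moved, native) == 0.0


def test_metrics_invariant_under_common_rigid_motion(native):
    decoy = make_decoy_cloud(native, 1, 6.0, seed=5, rot_deg=20.0)[0]
    l0, i0, f0 = ligand_rmsd(decoy, native), interface_rmsd(decoy, native), \
        fnat(decoy, native)
    R = rotation_about_axis(np.array([0.2, 1.0, 0.4]), 71.0)
    t = np.array([12.0, -5.0, 3.0])
    moved_decoy, moved_native = decoy.copy(), native.copy()
    for p in (moved_decoy, moved_native):
        p.transform_chains(list(p.chains), R, t)
    assert ligand_rmsd(moved_decoy, moved_native) == pytest.approx(l0, abs=1e-7)
    assert interface_rmsd(moved_decoy, moved_native) == pytest.approx(i0, abs=1e-7)
    assert fnat(moved_decoy, moved_native) == f0


def test_rmsd_metrics_match_brute_force_oracle(native):
    """Randomized decoys: package metrics equal an independent SVD-Kabsch
    brute-force implementation to 1e-6 A."""
    from snugdock.antibody import interface_residues
    from snugdock.structure import BACKBONE_NAMES

    decoys = make_decoy_cloud(native, 25, 8.0, seed=9, rot_deg=25.0)

    def backbone(pose, chains, keep=None):
        pts = []
        for cid in chains:
            for res in pose.chains[cid]:
                if keep is not None and (cid, res.number) not in keep:
                    continue
                for name in BACKBONE_NAMES:
                    pts.append(res.atom(name).coord)
        return np.array(pts)

    iface_ab, iface_ag = interface_residues(native, native.antibody_chains,
                                            native.antigen_chains, 10.0)
    iface = iface_ab | iface_ag
    for decoy in decoys:
        # ligand rmsd oracle: superpose antibody, apply to antigen
        R, t = kabsch_oracle(backbone(decoy, native.antibody_chains),
                             backbone(native, native.antibody_chains))
        ag_m = backbone(decoy, native.antigen_chains) @ R.T + t
        ag_n = backbone(native, native.antigen_chains)
        l_oracle = float(np.sqrt(np.mean(np.sum((ag_m - ag_n) ** 2, axis=1))))
        assert ligand_rmsd(decoy, native) == pytest.approx(l_oracle, abs=1e-6)

        i_oracle = brute_force_rmsd_after_superposition(
            backbone(decoy, list(native.chains), iface),
            backbone(native, list(native.chains), iface))
        assert interface_rmsd(decoy, native) == pytest.approx(i_oracle, abs=1e-6)


def test_fnat_matches_brute_force_enumeration(native):
    decoy = make_decoy_cloud(native, 1, 4.0, seed=3, rot_deg=15.0)[0]

    def contacts(pose):
        pairs = set()
        for c1 in pose.antibody_chains:
            for r1 in pose.chains[c1]:
                for c2 in pose.antigen_chains:
                    for r2 in pose.chains[c2]:
                        hit = any(
                            np.linalg.norm(a1.coord - a2.coord) <= 5.0
                            for a1 in r1.atoms if not a1.is_hydrogen
                            for a2 in r2.atoms if not a2.is_hydrogen)
                        if hit:
                            pairs.add(((c1, r1.number), (c2, r2.number)))
        return pairs

    ref, got = contacts(native), contacts(decoy)
    assert native_contacts(native) == ref
    assert fnat(decoy, native) == pytest.approx(len(ref & got) / len(ref), abs=1e-12)


def test_fnat_contact_flips_exactly_at_5A(native):
    """Sweeping a separation across 5.0 A flips a single contact on/off at
    the threshold."""
    from snugdock.structure import Atom, Pose, Residue

    def single(name, x, atom="CA"):
        return [Residue(1, name, [Atom.make(atom, [x, 0, 0])])]

    for d, expected in [(4.999, 1), (5.0, 1), (5.001, 0)]:
        pose = Pose({"L": single("GLY", 0.0), "H": single("GLY", 200.0),
                     "A": single("GLY", d)},
                    {"L": "light", "H": "heavy", "A": "antigen"})
        assert len(native_contacts(pose)) == expected


# ---- CAPRI -------------------------------------------------------------


@pytest.mark.parametrize("l,i,f,expected", [
    (8.9, 4.2, 0.39, "acceptable"),   # printed worked example
    (6.6, 3.5, 0.55, "medium"),       # printed worked example
    (0.5, 0.4, 0.9, "high"),
    (3.0, 1.5, 0.35, "medium"),
    (12.0, 5.0, 0.8, "incorrect"),    # both rmsd criteria fail badly
    (4.0, 1.8, 0.05, "incorrect"),
    (9.0, 3.9, 0.15, "acceptable"),
])
def test_capri_classification_table(l, i, f, expected):
    assert capri_rate(l, i, f).label == expected


def test_capri_zero_fnat_always_incorrect():
    for l, i in [(0.1, 0.1), (3.0, 2.0), (50.0, 20.0)]:
        assert capri_rate(l, i, 0.0).label == "incorrect"


def test_capri_monotone_in_fnat():
    for l, i in [(0.8, 0.5), (4.0, 1.9), (8.0, 3.0), (12.0, 5.0)]:
        ranks = [capri_rate(l, i, f).rank for f in np.linspace(0, 1, 101)]
        assert all(b >= a for a, b in zip(ranks, ranks[1:]))


def test_capri_medium_threshold_at_50_percent_for_2bdn_geometry():
    """At L=6.6, I=3.5 the rating reaches medium exactly at fnat = 0.50."""
    first = next(f for f in np.arange(0.0, 1.001, 0.01)
                 if capri_rate(6.6, 3.5, f).label == "medium")
    assert first == pytest.approx(0.50)


def test_capri_rejects_invalid_inputs():
    with pytest.raises(ValueError):
        capri_rate(np.nan, 1.0, 0.5)
    with pytest.raises(ValueError):
        capri_rate(1.0, 1.0, 1.5)


# ---- funnel ------------------------------------------------------------


def _entries(n_medium, n_total=20):
    """n_total decoys; the ten lowest energies contain n_medium mediums."""
    out = []
    for k in range(10):
        label = "medium" if k < n_medium else "incorrect"
        out.append((label, float(k)))
    out += [("high", 100.0 + k) for k in range(n_total - 10)]
    return out


def test_funnel_boundary_five_vs_four():
    assert detect_funnel(_entries(5)) is True
    assert detect_funnel(_entries(4)) is False


def test_funnel_counts_high_as_medium_or_better():
    entries = [("high", float(k)) for k in range(10)] + \
        [("incorrect", 50.0)] * 5
    assert detect_funnel(entries) is True
    # the strict reading counts only exact mediums
    assert detect_funnel(entries, strict_medium=True) is False


def test_funnel_requires_ten_decoys():
    with pytest.raises(ValueError):
        detect_funnel([("medium", 0.0)] * 9)


# ---- diversity and tables ---------------------------------------------


def test_diversity_zero_for_identical_decoys(native, paratope):
    df = diversity_stats([native.copy(), native.copy()], native, paratope)
    assert np.allclose(df["mean_rmsd"], 0.0, atol=1e-9)
    assert np.allclose(df["sd_rmsd"], 0.0, atol=1e-9)


def test_diversity_detects_single_translated_cdr(native, paratope):
    """Translating one CDR rigidly by 1 A shows up as exactly that loop's
    mean rmsd; other CDRs stay at zero."""
    lp = paratope.loop("H2")
    decoy = native.copy()
    for number in lp.residues():
        for a in decoy.residue(lp.chain, number).atoms:
            a.coord = a.coord + np.array([1.0, 0.0, 0.0])
    df = diversity_stats([decoy], native, paratope)
    assert df.loc["H2", "mean_rmsd"] == pytest.approx(1.0, abs=1e-9)
    for other in ("L1", "L2", "L3", "H1"):
        assert df.loc[other, "mean_rmsd"] == pytest.approx(0.0, abs=1e-9)


def test_diversity_matches_brute_force_segment_oracle(native, paratope):
    decoys = make_decoy_cloud(native, 3, 2.0, seed=21, rot_deg=10.0)
    # also wiggle the H3 loop so antibody segments differ
    from snugdock import build_loop_foldtree, small_move
    tree = build_loop_foldtree(native, paratope.loops)
    rng = np.random.default_rng(8)
    decoys = [small_move(d, tree, paratope.loop("H3"), 25.0, rng) for d in decoys]

    from snugdock.structure import BACKBONE_NAMES
    lp = paratope.loop("H3")
    fw = paratope.framework_heavy

    def seg(pose, numbers):
        return np.array([pose.residue(lp.chain, n).atom(a).coord
                         for n in sorted(numbers) for a in BACKBONE_NAMES])

    vals = []
    for d in decoys:
        R, t = kabsch_oracle(seg(d, fw), seg(native, fw))
        q = seg(d, lp.residues()) @ R.T + t
        vals.append(float(np.sqrt(np.mean(np.sum((q - seg(native, lp.residues())) ** 2,
                                                 axis=1)))))
    df = diversity_stats(decoys, native, paratope)
    assert df.loc["H3", "mean_rmsd"] == pytest.approx(np.mean(vals), abs=1e-6)
    assert df.loc["H3", "sd_rmsd"] == pytest.approx(np.std(vals), abs=1e-6)


def test_perturbation_table_shape_and_consistency(native, paratope):
    from snugdock import ProtocolConfig, run_simulation
    cfg = ProtocolConfig(n_decoys=2, low_res_cycles=2, high_res_cycles=2,
                         min_max_iter=2, seed=5)
    dset = run_simulation(native, None, paratope, cfg)
    from snugdock import perturbation_table
    df = perturbation_table(dset, native)
    assert len(df) == len(dset.decoys) + 1
    nat = df[df["decoy"] == "native"].iloc[0]
    assert nat["ligand_rmsd"] == 0.0
    for _, row in df[df["decoy"] != "native"].iterrows():
        assert capri_rate(row["ligand_rmsd"], row["interface_rmsd"],
                          row["fnat"]).label == row["rating"]
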