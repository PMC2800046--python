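import numpy as np
import pytest

from snugdock import (
    FixtureSpec,
    build_docking_foldtree,
    build_loop_foldtree,
    make_homology_mimic,
    make_toy_complex,
)


@pytest.fixture(scope="session")
def native_complex():
    """Toy antibody-antigen native complex (pose, paratope map)."""
    return make_toy_complex()


@pytest.fixture(scope="session")
def native(native_complex):
    return native_complex[0]


@pytest.fixture(scope="session")
def paratope(native_complex):
    return native_complex[1]


@pytest.fixture(scope="session")
def mimic_and_ensemble(native_complex):
    """Homology-model mimic with 2 A per-loop error and a 3-member ensemble."""
    native, paratope = native_complex
    spec = FixtureSpec(homology_error=2.0, ensemble_size=3, seed=3)
    return make_homology_mimic(native, paratope, spec)


@pytest.fixture(scope="session")
def mimic(mimic_and_ensemble):
    return mimic_and_ensemble[0]


@pytest.fixture()
def dock_tree(native):
    return build_docking_foldtree(native)


@pytest.fixture()
def loop_tree(native, paratope):
    return build_loop_foldtree(native, paratope.loops, allow_vl_vh=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


# ---- independent oracles ----------------------------------------------


def kabsch_oracle(mobile: np.ndarray, target: np.ndarray):
    """Hand-written SVD Kabsch with determinant correction (independent of
    the package's superposition route)."""
    mc, tc = mobile.mean(0), target.mean(0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, tc - R @ mc


def brute_force_rmsd_after_superposition(mobile, target):
    R, t = kabsch_oracle(mobile, target)
    moved = mobile @ R.T + t
    return float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))


def heavy_atoms(pose, chains):
    out = []
    for cid in chains:
        for res in pose.chains[cid]:
            for a in res.atoms:
                if not a.is_hydrogen:
                    out.append((cid, res.number, a.name, a.coord))
    return out
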