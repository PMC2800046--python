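"""Docking-quality metrics and CAPRI-style classification.

Conventions follow the community assessment rules: ligand rmsd is measured
over antigen backbone atoms (N, CA, C, O) after least-squares superposition of
the antibody backbone; interface rmsd is measured over the backbone atoms of
the native-complex interface (residues within 10 A of a heavy atom of the
other partner) after superposing those same atoms; fnat is the fraction of
native cross-partner residue contacts (any heavy-atom pair within 5 A)
recovered by the model.  The native complex alone defines the interface and
contact sets; models are queried against them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .antibody import ParatopeMap, interface_residues
from .geometry import kabsch_rotation, rmsd, superposed_rmsd
from .structure import BACKBONE_NAMES, Pose

CONTACT_CUTOFF = 5.0
INTERFACE_CUTOFF = 10.0

RATING_ORDER = {"incorrect": 0, "acceptable": 1, "medium": 2, "high": 3}


@dataclass(frozen=True)
class CapriRating:
    label: str

    def __post_init__(self):
        if self.label not in RATING_ORDER:
            raise ValueError(f"unknown rating {self.label!r}")

    @property
    def rank(self) -> int:
        return RATING_ORDER[self.label]


@dataclass
class MetricReport:
    ligand_rmsd: float
    interface_rmsd: float
    fnat: float
    rating: CapriRating


# ---- correspondence helpers -------------------------------------------


def _paired_backbone(model: Pose, native: Pose, chains,
                     residue_filter=None):
    """Matched backbone coordinate arrays (model, native) over the shared
    residues of the given chains; flagged residues are skipped."""
    mpts, npts, missing = [], [], []
    for cid in chains:
        native_res = {r.key: r for r in native.chains[cid]}
        for res in model.chains[cid]:
            key = (cid, res.number, res.icode)
            if key in model.flagged or (cid, res.number, res.icode) in native.flagged:
                continue
            if res.key not in native_res:
                missing.append(f"{cid}{res.number}{res.icode}")
                continue
            if residue_filter is not None and not residue_filter(cid, res.number):
                continue
            nres = native_res[res.key]
            for name in BACKBONE_NAMES:
                if res.has_atom(name) and nres.has_atom(name):
                    mpts.append(res.atom(name).coord)
                    npts.append(nres.atom(name).coord)
    if missing:
        raise ValueError(f"model residues absent from native: {missing}")
    if not mpts:
        raise ValueError("no paired backbone atoms")
    return np.array(mpts), np.array(npts)


def ligand_rmsd(model: Pose, native: Pose) -> float:
    """Antigen backbone rmsd after superposing the model's antibody backbone
    onto the native antibody backbone (no second superposition)."""
    ab_m, ab_n = _paired_backbone(model, native, native.antibody_chains)
    R, t = kabsch_rotation(ab_m, ab_n)
    ag_m, ag_n = _paired_backbone(model, native, native.antigen_chains)
    return rmsd(ag_m @ R.T + t, ag_n)


def interface_rmsd(model: Pose, native: Pose,
                   cutoff: float = INTERFACE_CUTOFF) -> float:
    """Backbone rmsd over the native interface residues after optimally
    superposing the model onto the native over those same atoms."""
    set_ab, set_ag = interface_residues(native, native.antibody_chains,
                                        native.antigen_chains, cutoff)
    iface = set_ab | set_ag
    if not iface:
        raise ValueError("native complex has no interface at the cutoff")
    m, n = _paired_backbone(model, native, list(native.chains),
                            residue_filter=lambda c, i: (c, i) in iface)
    return superposed_rmsd(m, n)


def native_contacts(pose: Pose, cutoff: float = CONTACT_CUTOFF):
    """Cross-partner residue contact pairs: ((ab_chain, num), (ag_chain, num))
    with any heavy-atom pair within ``cutoff``."""
    def collect(chains):
        pts, keys = [], []
        for cid, res, atom in pose.iter_atoms(chains):
            if atom.is_hydrogen:
                continue
            pts.append(atom.coord)
            keys.append((cid, res.number))
        return np.array(pts), keys

    pa, ka = collect(pose.antibody_chains)
    pb, kb = collect(pose.antigen_chains)
    pairs = set()
    hits = cKDTree(pa).query_ball_tree(cKDTree(pb), r=cutoff)
    for ia, lst in enumerate(hits):
        for ib in lst:
            pairs.add((ka[ia], kb[ib]))
    return pairs


def fnat(model: Pose, native: Pose, cutoff: float = CONTACT_CUTOFF) -> float:
    """Fraction of the native cross-partner residue contacts present in the
    model."""
    ref = native_contacts(native, cutoff)
    if not ref:
        raise ValueError("native complex has no cross-partner contacts")
    got = native_contacts(model, cutoff)
    return len(ref & got) / len(ref)


# ---- CAPRI classification ---------------------------------------------


def capri_rate(l_rms: float, i_rms: float, fnat_val: float) -> CapriRating:
    """Standard CAPRI quality table.

    incorrect: fnat < 0.1, or both rmsd criteria fail badly (L > 10 and I > 4);
    high:      fnat >= 0.5 and (L <= 1 or I <= 1);
    medium:    (fnat >= 0.3 and (L <= 5 or I <= 2)) or
               (fnat >= 0.5 and L > 1 and I > 1);
    acceptable otherwise, provided fnat >= 0.3, or fnat >= 0.1 with
               (L <= 10 or I <= 4).
    """
    if not (np.isfinite(l_rms) and np.isfinite(i_rms) and 0.0 <= fnat_val <= 1.0):
        raise ValueError("metrics must be finite with fnat in [0, 1]")
    if fnat_val < 0.1 or (l_rms > 10.0 and i_rms > 4.0):
        return CapriRating("incorrect")
    if fnat_val >= 0.5 and (l_rms <= 1.0 or i_rms <= 1.0):
        return CapriRating("high")
    if (fnat_val >= 0.3 and (l_rms <= 5.0 or i_rms <= 2.0)) or \
            (fnat_val >= 0.5 and l_rms > 1.0 and i_rms > 1.0):
        return CapriRating("medium")
    return CapriRating("acceptable")


def evaluate_decoy(model: Pose, native: Pose) -> MetricReport:
    l = ligand_rmsd(model, native)
    i = interface_rmsd(model, native)
    f = fnat(model, native)
    return MetricReport(l, i, f, capri_rate(l, i, f))


# ---- funnel and diversity ---------------------------------------------


def detect_funnel(entries, strict_medium: bool = False) -> bool:
    """True iff at least five of the ten lowest-energy decoys are of medium
    or better quality (``strict_medium`` counts exactly medium, the literal
    convergence wording).  ``entries`` is an iterable of (rating, energy)."""
    entries = [(r if isinstance(r, CapriRating) else CapriRating(r), e)
               for r, e in entries]
    if len(entries) < 10:
        raise ValueError("funnel detection needs at least 10 decoys")
    top10 = sorted(entries, key=lambda re: re[1])[:10]
    if strict_medium:
        n_good = sum(1 for r, _ in top10 if r.label == "medium")
    else:
        n_good = sum(1 for r, _ in top10 if r.rank >= RATING_ORDER["medium"])
    return n_good >= 5


def _segment_rmsd(decoy: Pose, start: Pose, superpose_sel, query_sel) -> float:
    sup_m, sup_n = _paired_backbone(decoy, start, list(start.chains),
                                    residue_filter=superpose_sel)
    R, t = kabsch_rotation(sup_m, sup_n)
    q_m, q_n = _paired_backbone(decoy, start, list(start.chains),
                                residue_filter=query_sel)
    return rmsd(q_m @ R.T + t, q_n)


def diversity_stats(decoys, start: Pose, paratope: ParatopeMap) -> pd.DataFrame:
    """Per-segment mean +/- SD backbone rmsd from the starting structure over
    a set of decoys (typically the ten lowest-energy ones).

    For each CDR the owning chain's framework is superposed and the rmsd is
    queried over the CDR; the V_L-V_H row superposes the light framework and
    queries the heavy framework; the paratope row superposes and queries the
    paratope itself.
    """
    light = start.chain_ids("light")
    heavy = start.chain_ids("heavy")
    fw_light = {(c, i) for c in light for i in paratope.framework_light}
    fw_heavy = {(c, i) for c in heavy for i in paratope.framework_heavy}
    par = paratope.paratope

    segments: dict[str, tuple] = {}
    for name, lp in paratope.loops.items():
        fw = fw_light if lp.chain in light else fw_heavy
        segments[name] = (lambda c, i, fw=fw: (c, i) in fw,
                          lambda c, i, lp=lp: c == lp.chain and lp.start <= i <= lp.stop)
    segments["vl_vh"] = (lambda c, i: (c, i) in fw_light,
                         lambda c, i: (c, i) in fw_heavy)
    segments["paratope"] = (lambda c, i: (c, i) in par,
                            lambda c, i: (c, i) in par)

    rows = []
    for name, (sup, query) in segments.items():
        vals = [_segment_rmsd(d, start, sup, query) for d in decoys]
        rows.append({"segment": name, "mean_rmsd": float(np.mean(vals)),
                     "sd_rmsd": float(np.std(vals))})
    return pd.DataFrame(rows).set_index("segment")


def perturbation_table(decoy_set, native: Pose, weights=None) -> pd.DataFrame:
    """One row per decoy (interface energy, total score, L_rms, I_rms, fnat,
    rating) plus a rescored-native reference row."""
    from .energetics import score

    rows = []
    for d in decoy_set.decoys:
        rep = evaluate_decoy(d.best_pose, native)
        rows.append({
            "decoy": d.index, "interface_energy": d.energy.interface_energy,
            "total": d.energy.total, "ligand_rmsd": rep.ligand_rmsd,
            "interface_rmsd": rep.interface_rmsd, "fnat": rep.fnat,
            "rating": rep.rating.label,
        })
    nat_energy = score(native, weights)
    rows.append({
        "decoy": "native", "interface_energy": nat_energy.interface_energy,
        "total": nat_energy.total, "ligand_rmsd": 0.0, "interface_rmsd": 0.0,
        "fnat": 1.0, "rating": "high",
    })
    return pd.DataFrame(rows)
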