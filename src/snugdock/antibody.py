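"""CDR loop bookkeeping and interface-residue detection.

The six complementarity-determining regions (L1-L3 on the light chain, H1-H3
on the heavy chain) are supplied explicitly via config -- Chothia-style ranges
are recommended -- rather than derived from sequence numbering.  The paratope
is the union of the six loops; everything else on the antibody chains is
framework, used for superposition and for freezing move maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .structure import Pose

LOOP_NAMES = ("L1", "L2", "L3", "H1", "H2", "H3")


@dataclass(frozen=True)
class LoopDefinition:
    """One CDR loop: inclusive residue-number range on its chain plus the
    fold-tree cutpoint (defaults to the loop middle)."""

    name: str
    chain: str
    start: int
    stop: int
    cutpoint: int

    def __post_init__(self):
        if self.name not in LOOP_NAMES:
            raise ValueError(f"unknown loop name {self.name!r}")
        if not self.start < self.stop:
            raise ValueError(f"loop {self.name}: start must be < stop")
        if not (self.start <= self.cutpoint < self.stop):
            raise ValueError(f"loop {self.name}: cutpoint must lie in [start, stop)")

    @property
    def length(self) -> int:
        return self.stop - self.start + 1

    def residues(self) -> list[int]:
        return list(range(self.start, self.stop + 1))


def default_cutpoint(start: int, stop: int) -> int:
    """Cut at the middle of the loop: start + floor((stop-start)/2)."""
    return start + (stop - start) // 2


@dataclass
class ParatopeMap:
    loops: dict[str, LoopDefinition]
    framework_light: set[int] = field(default_factory=set)
    framework_heavy: set[int] = field(default_factory=set)

    @property
    def paratope(self) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for lp in self.loops.values():
            out |= {(lp.chain, i) for i in lp.residues()}
        return out

    def loop(self, name: str) -> LoopDefinition:
        return self.loops[name]

    def loop_residues(self, name: str) -> set[tuple[str, int]]:
        lp = self.loops[name]
        return {(lp.chain, i) for i in lp.residues()}

    def framework(self, role: str) -> set[int]:
        return self.framework_light if role == "light" else self.framework_heavy


def load_loop_definitions(config, pose: Pose) -> ParatopeMap:
    """Validate a ``loops:`` config block against a pose.

    ``config`` is a path to a YAML file or an already-parsed mapping with a
    ``loops`` list of {name, chain, start, stop[, cutpoint]} entries.  All six
    CDRs must be present, lie inside their chains and be mutually disjoint.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    entries = config.get("loops", config)
    if isinstance(entries, dict):
        entries = [dict(v, name=k) for k, v in entries.items()]

    loops: dict[str, LoopDefinition] = {}
    for e in entries:
        cut = e.get("cutpoint")
        if cut is None:
            cut = default_cutpoint(e["start"], e["stop"])
        loops[e["name"]] = LoopDefinition(e["name"], e["chain"], e["start"], e["stop"], cut)

    missing = [n for n in LOOP_NAMES if n not in loops]
    if missing:
        raise ValueError(f"loop config missing CDRs: {missing}")
    h3 = loops["H3"]
    if not 7 <= h3.length <= 11:
        import logging
        logging.getLogger("snugdock").warning(
            "H3 length %d outside the 7-11 residue range the protocol was "
            "validated on", h3.length)

    light = pose.chain_ids("light")
    heavy = pose.chain_ids("heavy")
    occupied: dict[tuple[str, int], str] = {}
    for lp in loops.values():
        expected = light if lp.name.startswith("L") else heavy
        if lp.chain not in expected:
            raise ValueError(f"loop {lp.name}: chain {lp.chain} is not the "
                             f"{'light' if lp.name.startswith('L') else 'heavy'} chain")
        numbers = {r.number for r in pose.chains[lp.chain]}
        for i in lp.residues():
            if i not in numbers:
                raise ValueError(f"loop {lp.name}: residue {i} not in chain {lp.chain}")
            if (lp.chain, i) in occupied:
                raise ValueError(f"loops {occupied[(lp.chain, i)]} and {lp.name} overlap "
                                 f"at {lp.chain}{i}")
            occupied[(lp.chain, i)] = lp.name

    pm = ParatopeMap(loops)
    cdr = pm.paratope
    for cid in light:
        pm.framework_light |= {r.number for r in pose.chains[cid]
                               if (cid, r.number) not in cdr}
    for cid in heavy:
        pm.framework_heavy |= {r.number for r in pose.chains[cid]
                               if (cid, r.number) not in cdr}
    return pm


def interface_residues(pose: Pose, group_a, group_b, cutoff: float = 10.0):
    """Residues of each group with any non-hydrogen atom within ``cutoff`` of a
    non-hydrogen atom of the other group.

    ``group_a``/``group_b`` are chain-id iterables; returns two sets of
    (chain, residue number) keys, one per group.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    def collect(chains):
        pts, keys = [], []
        for cid, res, atom in pose.iter_atoms(chains):
            if atom.is_hydrogen:
                continue
            pts.append(atom.coord)
            keys.append((cid, res.number))
        return np.array(pts), keys

    pa, ka = collect(group_a)
    pb, kb = collect(group_b)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("a group has no heavy atoms")
    pairs = cKDTree(pa).query_ball_tree(cKDTree(pb), r=cutoff)
    set_a, set_b = set(), set()
    for ia, hits in enumerate(pairs):
        if hits:
            set_a.add(ka[ia])
            for ib in hits:
                set_b.add(kb[ib])
    return set_a, set_b
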