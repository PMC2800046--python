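"""Molecular data model and PDB I/O.

A :class:`Pose` holds an antibody Fv (light + heavy chains) plus an antigen as
an ordered map of chains, each a list of residues carrying explicit Cartesian
coordinates.  Poses exist in two resolutions: ``fullatom`` (all heavy atoms,
hydrogens optional) and ``centroid`` (backbone plus a single side-chain
pseudo-atom per residue, used by the coarse low-resolution docking stage).

Parsing goes through Bio.PDB; writing emits plain ATOM/TER records so that the
3-decimal coordinate contract is explicit.  Waters and HETATM records are
ignored, altlocs collapse to the highest-occupancy conformer, and insertion
codes are preserved as part of residue identity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .geometry import (
    ANGLE_N_CA_CB,
    BOND_CA_CB,
    measure_dihedral,
    place_atom,
)

logger = logging.getLogger("snugdock")

BACKBONE_NAMES = ("N", "CA", "C", "O")
PSEUDO_ATOM_NAME = "CEN"

#: Fixed per-element van der Waals radii (Angstrom); the pseudo-atom used in
#: centroid mode gets its own entry.
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2, "X": 2.0}

ROLES = ("light", "heavy", "antigen")

# Internal idealized side-chain templates: linear heavy-atom chains built off
# CA with standard bond lengths/angles and all-trans torsions.  Enough for the
# small residue alphabet the toy fixtures use; unknown residues fall back to a
# single CB.
SIDECHAIN_TEMPLATES = {
    "GLY": [],
    "ALA": [("CB", "C")],
    "SER": [("CB", "C"), ("OG", "O")],
    "CYS": [("CB", "C"), ("SG", "S")],
    "LYS": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("CE", "C"), ("NZ", "N")],
    "GLU": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("OE1", "O")],
    "ARG": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("NE", "N"), ("CZ", "C")],
}


def element_of(atom_name: str) -> str:
    name = atom_name.strip()
    if name == PSEUDO_ATOM_NAME:
        return "X"
    for ch in name:
        if ch.isalpha():
            el = ch.upper()
            break
    else:
        return "C"
    return el if el in VDW_RADII else "C"


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    is_backbone: bool = False
    is_hydrogen: bool = False
    vdw_radius: float = 1.7

    @classmethod
    def make(cls, name: str, coord, element: str | None = None) -> "Atom":
        el = element if element is not None else element_of(name)
        return cls(
            name=name,
            element=el,
            coord=np.asarray(coord, dtype=float).copy(),
            is_backbone=name in BACKBONE_NAMES,
            is_hydrogen=el == "H",
            vdw_radius=VDW_RADII.get(el, 1.7),
        )

    def copy(self) -> "Atom":
        return Atom(
            self.name, self.element, self.coord.copy(), self.is_backbone,
            self.is_hydrogen, self.vdw_radius,
        )


@dataclass
class Residue:
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.number}{self.icode}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def backbone_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_backbone]

    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_backbone and not a.is_hydrogen]

    def has_complete_backbone(self) -> bool:
        return all(self.has_atom(n) for n in BACKBONE_NAMES)

    def copy(self) -> "Residue":
        return Residue(self.number, self.name, [a.copy() for a in self.atoms], self.icode)


class Pose:
    """Chains -> residues -> atoms with a resolution flag and a role partition.

    ``partition`` maps chain id to one of ``light``/``heavy``/``antigen``; the
    antibody is the union of the light and heavy chains.
    """

    def __init__(self, chains: dict[str, list[Residue]], partition: dict[str, str],
                 resolution: str = "fullatom"):
        for cid, role in partition.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for chain {cid}")
        self.chains: dict[str, list[Residue]] = chains
        self.partition = dict(partition)
        self.resolution = resolution
        #: residues excluded from metric atom sets (incomplete backbone)
        self.flagged: set[tuple[str, int, str]] = set()

    # ---- basic access -------------------------------------------------
    def chain_ids(self, role: str | None = None) -> list[str]:
        if role is None:
            return list(self.chains)
        return [c for c in self.chains if self.partition.get(c) == role]

    @property
    def antibody_chains(self) -> list[str]:
        return self.chain_ids("light") + self.chain_ids("heavy")

    @property
    def antigen_chains(self) -> list[str]:
        return self.chain_ids("antigen")

    def residue(self, chain: str, number: int, icode: str = "") -> Residue:
        for r in self.chains[chain]:
            if r.number == number and r.icode == icode:
                return r
        raise KeyError(f"chain {chain}: no residue {number}{icode}")

    def residue_index(self, chain: str, number: int, icode: str = "") -> int:
        for i, r in enumerate(self.chains[chain]):
            if r.number == number and r.icode == icode:
                return i
        raise KeyError(f"chain {chain}: no residue {number}{icode}")

    def iter_residues(self, chain_ids=None):
        for cid in (chain_ids if chain_ids is not None else self.chains):
            for res in self.chains[cid]:
                yield cid, res

    def iter_atoms(self, chain_ids=None):
        for cid, res in self.iter_residues(chain_ids):
            for atom in res.atoms:
                yield cid, res, atom

    def coords(self, chain_ids=None, heavy_only: bool = False) -> np.ndarray:
        pts = [a.coord for _, _, a in self.iter_atoms(chain_ids)
               if not (heavy_only and a.is_hydrogen)]
        return np.array(pts) if pts else np.empty((0, 3))

    def backbone_coords(self, chain_ids=None, skip_flagged: bool = True) -> np.ndarray:
        pts = []
        for cid, res in self.iter_residues(chain_ids):
            if skip_flagged and (cid, res.number, res.icode) in self.flagged:
                continue
            for name in BACKBONE_NAMES:
                if res.has_atom(name):
                    pts.append(res.atom(name).coord)
        return np.array(pts) if pts else np.empty((0, 3))

    def center_of_mass(self, chain_ids=None) -> np.ndarray:
        c = self.coords(chain_ids, heavy_only=True)
        if len(c) == 0:
            raise ValueError("no atoms in selection")
        return c.mean(axis=0)

    def transform_chains(self, chain_ids, R: np.ndarray, t: np.ndarray) -> None:
        """Apply x -> R x + t in place to every atom of the named chains."""
        atoms = [a for _, _, a in self.iter_atoms(list(chain_ids))]
        pts = np.array([a.coord for a in atoms]) @ R.T + t
        for a, p in zip(atoms, pts):
            a.coord = p

    def copy(self) -> "Pose":
        p = Pose({c: [r.copy() for r in rs] for c, rs in self.chains.items()},
                 self.partition, self.resolution)
        p.flagged = set(self.flagged)
        return p

    # ---- torsions ------------------------------------------------------
    def backbone_torsion(self, chain: str, pos: int, angle_name: str) -> float:
        """phi/psi/omega (degrees) of the residue at list position ``pos``."""
        residues = self.chains[chain]
        r = residues[pos]
        if angle_name == "phi":
            if pos == 0:
                raise ValueError("phi undefined for first residue")
            prev = residues[pos - 1]
            return measure_dihedral(prev.atom("C").coord, r.atom("N").coord,
                                    r.atom("CA").coord, r.atom("C").coord)
        if angle_name == "psi":
            if pos == len(residues) - 1:
                raise ValueError("psi undefined for last residue")
            nxt = residues[pos + 1]
            return measure_dihedral(r.atom("N").coord, r.atom("CA").coord,
                                    r.atom("C").coord, nxt.atom("N").coord)
        if angle_name == "omega":
            if pos == len(residues) - 1:
                raise ValueError("omega undefined for last residue")
            nxt = residues[pos + 1]
            return measure_dihedral(r.atom("CA").coord, r.atom("C").coord,
                                    nxt.atom("N").coord, nxt.atom("CA").coord)
        raise ValueError(f"unknown torsion {angle_name!r}")

    def validate(self) -> None:
        if not self.antibody_chains or not self.antigen_chains:
            raise ValueError("pose must contain antibody (light+heavy) and antigen chains")
        for cid, residues in self.chains.items():
            keys = [(r.number, r.icode) for r in residues]
            nums = [r.number for r in residues]
            if nums != sorted(nums):
                raise ValueError(f"chain {cid}: residue numbers not increasing")
            if len(set(keys)) != len(keys):
                raise ValueError(f"chain {cid}: duplicate residue identities")


# ---- PDB I/O ----------------------------------------------------------


def read_pdb(path, partition: dict[str, str]) -> Pose:
    """Read a PDB file into a full-atom Pose.

    ``partition`` names the chains to load and their roles.  Waters and
    hetero records are dropped; altlocs collapse to the highest-occupancy
    conformer; residues missing any backbone atom are kept but flagged so
    metric atom sets skip them.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        model = parser.get_structure("pose", str(path))[0]
    present = {ch.id for ch in model}
    missing = set(partition) - present
    if missing:
        raise ValueError(f"chains missing from {path}: {sorted(missing)}")

    chains: dict[str, list[Residue]] = {}
    pose = Pose.__new__(Pose)
    flagged: set[tuple[str, int, str]] = set()
    for cid, role in partition.items():
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r} for chain {cid}")
        residues = []
        for res in model[cid]:
            hetflag, number, icode = res.id
            if hetflag.strip():  # waters + HETATM
                continue
            icode = icode.strip()
            atoms = []
            for at in res:
                if at.is_disordered():
                    children = sorted(at.disordered_get_list(),
                                      key=lambda a: a.get_occupancy() or 0.0)
                    at = children[-1]
                atoms.append(Atom.make(at.get_name(), np.asarray(at.get_coord(), float)))
            r = Residue(number, res.get_resname(), atoms, icode)
            if not r.has_complete_backbone():
                flagged.add((cid, number, icode))
                logger.warning("residue %s %s%d%s missing backbone atoms; "
                               "excluded from metric atom sets",
                               cid, r.name, number, icode)
            residues.append(r)
        chains[cid] = residues
    pose.__init__(chains, partition, resolution="fullatom")
    pose.flagged = flagged
    return pose


def write_pdb(pose: Pose, path) -> None:
    """Write standard ATOM/TER records; coordinates to 3 decimals."""
    if not any(pose.chains.values()):
        raise ValueError("refusing to write an empty pose")
    serial = 1
    lines = []
    for cid, residues in pose.chains.items():
        if not residues:
            raise ValueError(f"chain {cid} is empty")
        for res in residues:
            for a in res.atoms:
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4.4s} {res.name:<3.3s} {cid}"
                    f"{res.number:4d}{(res.icode or ' '):1.1s}"
                    f"   {a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element if a.element != 'X' else 'C':>2.2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {residues[-1].name:<3.3s} {cid}"
                     f"{residues[-1].number:4d}")
        serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---- resolution switching ---------------------------------------------


def to_centroid(pose: Pose) -> Pose:
    """Coarse-grain: replace each side chain by one pseudo-atom at its heavy-
    atom geometric center (the CA position for glycine); drop hydrogens."""
    if pose.resolution == "centroid":
        logger.warning("to_centroid: pose already centroid; no-op")
        return pose.copy()
    out = pose.copy()
    out.resolution = "centroid"
    for _, res in out.iter_residues():
        backbone = [a for a in res.atoms if a.is_backbone]
        side = [a for a in res.atoms if not a.is_backbone and not a.is_hydrogen]
        if side:
            center = np.mean([a.coord for a in side], axis=0)
        else:  # glycine
            center = res.atom("CA").coord.copy()
        res.atoms = backbone + [Atom.make(PSEUDO_ATOM_NAME, center, element="X")]
    return out


def _ideal_sidechain(res: Residue) -> list[Atom]:
    template = SIDECHAIN_TEMPLATES.get(res.name, [("CB", "C")])
    if not template:
        return []
    n, ca, c = (res.atom(x).coord for x in ("N", "CA", "C"))
    atoms: list[Atom] = []
    # CB off CA with tetrahedral geometry; remaining atoms all-trans.
    prev3 = (c, n, ca)
    coord = place_atom(*prev3, BOND_CA_CB, ANGLE_N_CA_CB, -122.0)
    atoms.append(Atom.make(template[0][0], coord, element=template[0][1]))
    chain = [n, ca, coord]
    for name, el in template[1:]:
        coord = place_atom(chain[-3], chain[-2], chain[-1], 1.52, 111.0, 180.0)
        atoms.append(Atom.make(name, coord, element=el))
        chain.append(coord)
    return atoms


def to_fullatom(pose: Pose, sidechain_source: dict[str, Pose] | None = None) -> Pose:
    """Rebuild full-atom side chains on a centroid pose.

    ``sidechain_source`` maps chain id to a donor full-atom pose with the same
    residue layout; each donor side chain is grafted by superposing the donor
    backbone (N, CA, C) onto the current backbone of that residue.  Residues
    without a donor get idealized template side chains.
    """
    if pose.resolution != "centroid":
        raise ValueError("to_fullatom expects a centroid pose")
    sidechain_source = sidechain_source or {}
    out = pose.copy()
    out.resolution = "fullatom"
    for cid, res in out.iter_residues():
        res.atoms = [a for a in res.atoms if a.is_backbone]
        donor_pose = sidechain_source.get(cid)
        if donor_pose is not None:
            donor = donor_pose.residue(cid, res.number, res.icode)
            if donor.name != res.name:
                raise ValueError(
                    f"donor residue mismatch at {cid}{res.number}: "
                    f"{donor.name} vs {res.name}")
            side = donor.sidechain_atoms()
            if side:
                names = ("N", "CA", "C")
                src = np.array([donor.atom(x).coord for x in names])
                dst = np.array([res.atom(x).coord for x in names])
                from .geometry import kabsch_rotation
                R, t = kabsch_rotation(src, dst)
                for a in side:
                    res.atoms.append(Atom.make(a.name, R @ a.coord + t, element=a.element))
        else:
            res.atoms.extend(_ideal_sidechain(res))
    return out
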