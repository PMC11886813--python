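"""Amino-acid constants and idealized residue templates.

Templates are loaded from the vendored plain-text data file
``data/residue_topology.json`` (schema documented in the file header).  Each
template carries the canonical atom14 layout, the chi-angle atom quadruples,
per-chi pi-symmetry flags, internal-coordinate build records for every
side-chain heavy atom, and derived bookkeeping (rotating masks, bond list)
used by kinematics, evaluation and I/O.

atom14 layout: slots 0-3 are always N, CA, C, O; slot 4 is CB for all
residues except GLY; remaining slots hold side-chain atoms in build order.
OXT and hydrogens are excluded throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

# aatype indices: alphabetical by three-letter code; 20 = unknown (UNK)
AA3 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
AA1 = list("ARNDCQEGHILKMFPSTWYV")
UNK_INDEX = 20
NUM_AA_CLASSES = 21  # 20 canonical + unknown

AA3_TO_INDEX = {a: i for i, a in enumerate(AA3)}
AA1_TO_INDEX = {a: i for i, a in enumerate(AA1)}
AA1_TO_AA3 = dict(zip(AA1, AA3))
AA3_TO_AA1 = dict(zip(AA3, AA1))

#: residue types that carry at least one chi angle (18 of 20)
CHI_BEARING = [a for a in AA3 if a not in ("ALA", "GLY")]

BACKBONE_ATOMS = ["N", "CA", "C", "O"]
MAX_CHI = 4
ATOM14 = 14


@dataclass(frozen=True)
class SidechainAtom:
    """One internal-coordinate build record (NeRF placement)."""

    name: str
    slot: int                 # atom14 slot of this atom
    frame: tuple              # atom14 slots (p3, p2, p1); p1 is the bond partner
    bond: float               # Angstrom
    angle: float              # radians, p2-p1-self
    kind: str                 # "chi" | "chi+" | "fixed"
    chi_index: int            # 0-based, -1 for fixed
    offset: float             # radians added to chi (or the fixed dihedral)


@dataclass(frozen=True)
class ResidueTemplate:
    name: str
    index: int
    atom14_names: tuple                  # length <= 14, padded externally
    num_chi: int
    chi_atom_slots: np.ndarray           # (4, 4) int, -1 padded
    chi_symmetric: np.ndarray            # (4,) bool
    sidechain: tuple                     # SidechainAtom records, build order
    rotating_masks: np.ndarray           # (4, 14) bool: atoms moved by chi_k
    bonds: tuple                         # intra-residue bonded slot pairs
    atom_exists: np.ndarray = field(default=None)  # (14,) bool

    @property
    def chi_mask(self):
        m = np.zeros(MAX_CHI, dtype=bool)
        m[: self.num_chi] = True
        return m


def _load_raw():
    with resources.files("chiflow.data").joinpath("residue_topology.json").open() as fh:
        return json.load(fh)


_RAW = _load_raw()

#: ideal CB construction: frame (C, N, CA), bond/angle/improper dihedral
CBETA_FRAME = tuple(_RAW["cbeta"]["frame"])
CBETA_BOND = float(_RAW["cbeta"]["bond"])
CBETA_ANGLE = np.deg2rad(float(_RAW["cbeta"]["angle"]))
CBETA_DIHEDRAL = np.deg2rad(float(_RAW["cbeta"]["dihedral"]))


def _build_template(name, raw):
    atom_names = list(raw["atom14"])
    slot = {a: i for i, a in enumerate(atom_names)}
    n_chi = len(raw["chi_atoms"])

    chi_slots = np.full((MAX_CHI, 4), -1, dtype=int)
    for k, quad in enumerate(raw["chi_atoms"]):
        chi_slots[k] = [slot[a] for a in quad]

    sym = np.zeros(MAX_CHI, dtype=bool)
    sym[:n_chi] = raw["chi_symmetric"]

    side = []
    for rec in raw["sidechain"]:
        aname, frame, bond, angle, kind = rec[0], rec[1], rec[2], rec[3], rec[4]
        if kind == "chi":
            ci, off = rec[5] - 1, 0.0
        elif kind == "chi+":
            ci, off = rec[5] - 1, np.deg2rad(rec[6])
        else:  # fixed
            ci, off = -1, np.deg2rad(rec[5])
        side.append(
            SidechainAtom(
                name=aname,
                slot=slot[aname],
                frame=tuple(slot[a] for a in frame),
                bond=float(bond),
                angle=np.deg2rad(float(angle)),
                kind=kind,
                chi_index=ci,
                offset=float(off),
            )
        )

    # rotating masks: an atom moves under chi_k if its dihedral references
    # chi_k or any of its frame atoms moves (transitive, in build order)
    masks = np.zeros((MAX_CHI, ATOM14), dtype=bool)
    for k in range(n_chi):
        moved = set()
        for rec in side:
            if (rec.kind in ("chi", "chi+") and rec.chi_index == k) or any(
                f in moved for f in rec.frame
            ):
                moved.add(rec.slot)
        masks[k, sorted(moved)] = True

    bonds = [tuple(slot[a] for a in b) for b in _RAW["backbone_bonds"] if all(a in slot for a in b)]
    for rec in side:
        bonds.append((rec.frame[2], rec.slot))
    for pair in raw["closure_bonds"]:
        bonds.append((slot[pair[0]], slot[pair[1]]))

    exists = np.zeros(ATOM14, dtype=bool)
    exists[: len(atom_names)] = True

    return ResidueTemplate(
        name=name,
        index=AA3_TO_INDEX[name],
        atom14_names=tuple(atom_names),
        num_chi=n_chi,
        chi_atom_slots=chi_slots,
        chi_symmetric=sym,
        sidechain=tuple(side),
        rotating_masks=masks,
        bonds=tuple(bonds),
        atom_exists=exists,
    )


TEMPLATES = {name: _build_template(name, raw) for name, raw in _RAW["residues"].items()}
TEMPLATES_BY_INDEX = [TEMPLATES[a] for a in AA3]

# (20, 4) arrays used for vectorized masking
CHI_EXISTS = np.stack([t.chi_mask for t in TEMPLATES_BY_INDEX])
CHI_SYMMETRIC = np.stack([t.chi_symmetric for t in TEMPLATES_BY_INDEX])
NUM_CHI = np.array([t.num_chi for t in TEMPLATES_BY_INDEX])


def template_for(aa) -> ResidueTemplate:
    """Template lookup by index, one- or three-letter code."""
    if isinstance(aa, str):
        key = aa.upper()
        if len(key) == 1:
            key = AA1_TO_AA3.get(key, key)
        if key not in TEMPLATES:
            raise KeyError(f"unknown residue type {aa!r}")
        return TEMPLATES[key]
    if not 0 <= int(aa) < len(AA3):
        raise KeyError(f"unknown residue index {aa!r}")
    return TEMPLATES_BY_INDEX[int(aa)]


def chi_exists_mask(aatype):
    """(R, 4) existence mask for chi angles; unknown residues get none."""
    aatype = np.asarray(aatype)
    out = np.zeros(aatype.shape + (MAX_CHI,), dtype=bool)
    known = aatype < len(AA3)
    out[known] = CHI_EXISTS[aatype[known]]
    return out


def chi_symmetry_mask(aatype, enabled=True):
    """(R, 4) pi-symmetry flags (ASP/PHE/TYR chi2, GLU chi3 by default).

    ``enabled=False`` switches every angle to the full 2*pi period, for
    users preferring an alternate symmetry convention.
    """
    aatype = np.asarray(aatype)
    out = np.zeros(aatype.shape + (MAX_CHI,), dtype=bool)
    if enabled:
        known = aatype < len(AA3)
        out[known] = CHI_SYMMETRIC[aatype[known]]
    return out
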