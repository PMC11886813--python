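"""In-memory containers: per-residue chi-angle sets and protein structures."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import residues
from .torus import TWO_PI


@dataclass
class ChiSet:
    """Per-residue side-chain torsions: the flow's state space.

    angles : (R, 4) radians.  Symmetry-reduced entries live in [0, pi),
        all others in [-pi, pi).  Masked-out entries are ignored by every
        consumer and conventionally zero.
    exists : (R, 4) bool, True where the residue type has that chi.
    symmetric : (R, 4) bool, True for pi-periodic angles.
    """

    angles: np.ndarray
    exists: np.ndarray
    symmetric: np.ndarray

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.exists = np.asarray(self.exists, dtype=bool)
        self.symmetric = np.asarray(self.symmetric, dtype=bool)
        if not (self.angles.shape == self.exists.shape == self.symmetric.shape):
            raise ValueError("ChiSet field shapes disagree")

    @property
    def num_residues(self):
        return self.angles.shape[0]

    @property
    def periods(self):
        """(R, 4) per-angle period: pi where symmetric, else 2*pi."""
        return np.where(self.symmetric, np.pi, TWO_PI)

    def copy(self):
        return ChiSet(self.angles.copy(), self.exists.copy(), self.symmetric.copy())

    @classmethod
    def empty(cls, aatype, symmetry_enabled=True):
        aatype = np.asarray(aatype)
        exists = residues.chi_exists_mask(aatype)
        sym = residues.chi_symmetry_mask(aatype, enabled=symmetry_enabled)
        return cls(np.zeros(exists.shape), exists, sym)


@dataclass
class StructureRecord:
    """One (possibly multi-chain) protein with atom14 coordinates.

    aatype : (R,) int, 0..19 canonical (alphabetical 3-letter order), 20 unknown.
    chain_ids : (R,) chain label per residue.
    backbone : (R, 4, 3) Angstrom, N/CA/C/O.
    atom14 : (R, 14, 3) Angstrom in the canonical per-residue slot order.
    atom_mask : (R, 14) bool, True where the slot is occupied.
    resolved_mask : (R,) bool, False for residues dropped by filtering.
    residue_numbers : (R,) author-assigned numbering (metadata for I/O).
    insertion_codes : (R,) author insertion codes (metadata for I/O).
    """

    aatype: np.ndarray
    chain_ids: np.ndarray
    backbone: np.ndarray
    atom14: np.ndarray
    atom_mask: np.ndarray
    resolved_mask: np.ndarray = None
    residue_numbers: np.ndarray = None
    insertion_codes: np.ndarray = None
    name: str = ""

    def __post_init__(self):
        self.aatype = np.asarray(self.aatype, dtype=int)
        self.chain_ids = np.asarray(self.chain_ids)
        self.backbone = np.asarray(self.backbone, dtype=float)
        self.atom14 = np.asarray(self.atom14, dtype=float)
        self.atom_mask = np.asarray(self.atom_mask, dtype=bool)
        r = self.num_residues
        if self.resolved_mask is None:
            self.resolved_mask = np.ones(r, dtype=bool)
        if self.residue_numbers is None:
            self.residue_numbers = np.arange(1, r + 1)
        if self.insertion_codes is None:
            self.insertion_codes = np.array([""] * r, dtype=object)
        self.resolved_mask = np.asarray(self.resolved_mask, dtype=bool)

    @property
    def num_residues(self):
        return self.aatype.shape[0]

    @property
    def sequence(self):
        """One-letter sequence string ('X' for unknown residues)."""
        return "".join(
            residues.AA1[a] if a < len(residues.AA1) else "X" for a in self.aatype
        )

    def subset(self, keep):
        """New record restricted to residue indices/boolean mask ``keep``."""
        keep = np.asarray(keep)
        return StructureRecord(
            aatype=self.aatype[keep],
            chain_ids=self.chain_ids[keep],
            backbone=self.backbone[keep],
            atom14=self.atom14[keep],
            atom_mask=self.atom_mask[keep],
            resolved_mask=self.resolved_mask[keep],
            residue_numbers=np.asarray(self.residue_numbers)[keep],
            insertion_codes=np.asarray(self.insertion_codes)[keep],
            name=self.name,
        )

    def copy(self):
        return StructureRecord(
            aatype=self.aatype.copy(),
            chain_ids=self.chain_ids.copy(),
            backbone=self.backbone.copy(),
            atom14=self.atom14.copy(),
            atom_mask=self.atom_mask.copy(),
            resolved_mask=self.resolved_mask.copy(),
            residue_numbers=np.asarray(self.residue_numbers).copy(),
            insertion_codes=np.asarray(self.insertion_codes).copy(),
            name=self.name,
        )
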