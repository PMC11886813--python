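"""Deterministic synthetic mini-proteins for desk-scale experiments.

Real structure datasets need downloads and curation; everything in this
package is instead exercised on synthetic single- and multi-chain proteins
with ideal backbone geometry and known side-chain chi angles.  Backbones
are grown residue-by-residue with ideal bond lengths/angles at canonical
(phi, psi) values per secondary-structure class; side chains are drawn from
a small discrete rotamer set (gauche+/gauche-/trans) with Gaussian jitter
and built with :func:`chiflow.kinematics.build_atoms`, so the ground-truth
ChiSet is known exactly by construction.

These fixtures emulate the *geometry* of real proteins, not their rotamer
statistics or packing energetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import residues
from .kinematics import build_atoms, nerf_place
from .records import ChiSet, StructureRecord
from .torus import wrap

__all__ = ["FixtureSpec", "make_backbone", "make_full_structure", "write_chi_table", "read_chi_table"]

# ideal trans-peptide geometry (Angstrom / degrees)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = np.deg2rad(111.0)
_ANGLE_CA_C_N = np.deg2rad(116.2)
_ANGLE_C_N_CA = np.deg2rad(121.7)
_ANGLE_CA_C_O = np.deg2rad(120.5)
_OMEGA = np.pi

#: canonical (phi, psi) in degrees per secondary-structure class
CANONICAL_PHI_PSI = {"helix": (-57.0, -47.0), "strand": (-139.0, 135.0)}

#: default rotamer centers (degrees) and jitter, see docs/methods.md
DEFAULT_ROTAMERS = (-60.0, 60.0, 180.0)
DEFAULT_JITTER_DEG = 5.0

#: inter-chain bounding-box gap; exceeds twice the maximal side-chain reach
_CHAIN_GAP = 16.0

_CHAIN_LABELS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class FixtureSpec:
    """Recipe for one synthetic protein; fully determined by its seeds."""

    length: int = 40
    chains: int = 1
    sequence_seed: int = 0
    rotamer_seed: int = 0
    secondary_structure: str = "mixed"  # helix | strand | mixed

    def __post_init__(self):
        if self.length < 2:
            raise ValueError("fixture length must be >= 2")
        if self.secondary_structure not in ("helix", "strand", "mixed"):
            raise ValueError(f"unknown secondary structure {self.secondary_structure!r}")


def _phi_psi_schedule(spec: FixtureSpec, rng):
    """(phi, psi) per residue of one chain, radians."""
    n = spec.length
    if spec.secondary_structure in CANONICAL_PHI_PSI:
        phi, psi = CANONICAL_PHI_PSI[spec.secondary_structure]
        kinds = [spec.secondary_structure] * n
    else:
        # mixed: alternate helix/strand segments of 8-12 residues
        kinds = []
        kind = "helix" if rng.integers(2) == 0 else "strand"
        while len(kinds) < n:
            kinds.extend([kind] * int(rng.integers(8, 13)))
            kind = "strand" if kind == "helix" else "helix"
        kinds = kinds[:n]
    sched = np.array([CANONICAL_PHI_PSI[k] for k in kinds])
    return np.deg2rad(sched[:, 0]), np.deg2rad(sched[:, 1])


def _grow_chain(phi, psi):
    """Grow one chain's (R, 4, 3) backbone by NeRF along the peptide."""
    n = len(phi)
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [_BOND_N_CA, 0.0, 0.0]
    ang = np.pi - _ANGLE_N_CA_C
    C[0] = CA[0] + _BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        N[i] = nerf_place(N[i - 1], CA[i - 1], C[i - 1], _BOND_C_N, _ANGLE_CA_C_N, psi[i - 1])
        CA[i] = nerf_place(CA[i - 1], C[i - 1], N[i], _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA)
        C[i] = nerf_place(C[i - 1], N[i], CA[i], _BOND_CA_C, _ANGLE_N_CA_C, phi[i])
    O = nerf_place(N, CA, C, _BOND_C_O, _ANGLE_CA_C_O, psi + np.pi)
    return np.stack([N, CA, C, O], axis=1)


def make_backbone(spec: FixtureSpec) -> StructureRecord:
    """Ideal-geometry backbone (atom14 side chains absent).

    Multi-chain specs lay chains side by side along x with a bounding-box
    gap large enough that even fully extended side chains cannot clash
    across chains.
    """
    rng = np.random.default_rng([int(spec.sequence_seed), 101])
    chains = []
    labels = []
    offset_x = 0.0
    for ci in range(spec.chains):
        phi, psi = _phi_psi_schedule(spec, rng)
        bb = _grow_chain(phi, psi)
        bb = bb - bb.reshape(-1, 3).min(axis=0)
        bb[..., 0] += offset_x
        offset_x = bb[..., 0].max() + _CHAIN_GAP
        chains.append(bb)
        labels.extend([_CHAIN_LABELS[ci % len(_CHAIN_LABELS)]] * spec.length)

    backbone = np.concatenate(chains, axis=0)
    R = backbone.shape[0]
    aatype = np.full(R, residues.AA3_TO_INDEX["GLY"])
    atom14 = np.zeros((R, 14, 3))
    atom14[:, :4] = backbone
    mask = np.zeros((R, 14), dtype=bool)
    mask[:, :4] = True
    numbers = np.concatenate([np.arange(1, spec.length + 1)] * spec.chains)
    return StructureRecord(
        aatype=aatype,
        chain_ids=np.array(labels),
        backbone=backbone,
        atom14=atom14,
        atom_mask=mask,
        residue_numbers=numbers,
        name=f"fixture-{spec.secondary_structure}-L{spec.length}x{spec.chains}",
    )


def _sample_sequence(spec: FixtureSpec, rng):
    """Random sequence guaranteed to contain every chi-bearing residue type
    (when long enough) and never collapse to an ALA/GLY-only chain."""
    R = spec.length * spec.chains
    bearing = [residues.AA3_TO_INDEX[a] for a in residues.CHI_BEARING]
    seq = list(rng.permutation(bearing)[: min(R, len(bearing))])
    while len(seq) < R:
        seq.append(int(rng.integers(0, 20)))
    seq = np.array(seq)
    rng.shuffle(seq)
    return seq


def _sample_chi(aatype, rng, rotamers, jitter_deg):
    exists = residues.chi_exists_mask(aatype)
    sym = residues.chi_symmetry_mask(aatype)
    centers = np.deg2rad(np.asarray(rotamers, dtype=float))
    pick = centers[rng.integers(0, len(centers), size=exists.shape)]
    ang = pick + np.deg2rad(jitter_deg) * rng.standard_normal(exists.shape)
    period = np.where(sym, np.pi, 2 * np.pi)
    ang = wrap(ang, period) * exists
    return ChiSet(ang, exists, sym)


def make_full_structure(
    spec: FixtureSpec,
    rotamers=DEFAULT_ROTAMERS,
    jitter_deg=DEFAULT_JITTER_DEG,
    sequence=None,
):
    """Full-atom fixture: (StructureRecord, ground-truth ChiSet).

    Chi angles are drawn per residue from ``rotamers`` (degrees) with
    Gaussian jitter of ``jitter_deg``; pi-symmetric angles are stored in
    their reduced [0, pi) chart.  ``sequence`` (a one-letter string)
    overrides the random sequence; ``rotamers=(180.,)`` yields fully
    extended side chains.  Small-residue sequences in extended strands are
    sterically clash-free by construction.
    """
    record = make_backbone(spec)
    seq_rng = np.random.default_rng([int(spec.sequence_seed), 11])
    rot_rng = np.random.default_rng([int(spec.rotamer_seed), 13])
    if sequence is not None:
        if len(sequence) != record.num_residues:
            raise ValueError("sequence length does not match spec")
        record.aatype = np.array([residues.AA1_TO_INDEX[c] for c in sequence.upper()])
    else:
        record.aatype = _sample_sequence(spec, seq_rng)
    chiset = _sample_chi(record.aatype, rot_rng, rotamers, jitter_deg)
    atom14, mask = build_atoms(record.backbone, record.aatype, chiset.angles)
    record.atom14 = atom14
    record.atom_mask = mask
    return record, chiset


def write_chi_table(path, record: StructureRecord, chiset: ChiSet):
    """Sidecar ground-truth table (TSV): chain, resid, aa, chi1-4 (deg), mask."""
    with open(path, "w") as fh:
        fh.write("chain\tresid\taa\tchi1\tchi2\tchi3\tchi4\tmask\n")
        deg = np.rad2deg(chiset.angles)
        for i in range(record.num_residues):
            aa = residues.AA3[record.aatype[i]] if record.aatype[i] < 20 else "UNK"
            vals = "\t".join(
                f"{deg[i, k]:.4f}" if chiset.exists[i, k] else "." for k in range(4)
            )
            m = "".join("1" if e else "0" for e in chiset.exists[i])
            fh.write(
                f"{record.chain_ids[i]}\t{record.residue_numbers[i]}\t{aa}\t{vals}\t{m}\n"
            )


def read_chi_table(path, aatype=None):
    """Read a sidecar chi table back into a ChiSet (angles in radians)."""
    angles, exists, aas = [], [], []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            aas.append(residues.AA3_TO_INDEX.get(parts[2], residues.UNK_INDEX))
            mask = np.array([c == "1" for c in parts[7]])
            row = np.array([float(v) if v != "." else 0.0 for v in parts[3:7]])
            angles.append(np.deg2rad(row))
            exists.append(mask)
    aas = np.array(aas) if aatype is None else np.asarray(aatype)
    sym = residues.chi_symmetry_mask(aas)
    return ChiSet(np.array(angles), np.array(exists), sym)
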