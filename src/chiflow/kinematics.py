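"""Chi-angle measurement and idealized full-atom reconstruction.

Under idealized bond lengths and angles, the side-chain conformation of a
residue is fully determined by its backbone frame and up to four chi
dihedrals.  This module converts between the two representations:

* :func:`measure_chi` reads chi angles off atom14 coordinates, and
* :func:`build_atoms` places idealized side-chain heavy atoms from the
  backbone and a chi vector by sequential internal-coordinate (NeRF)
  construction along the vendored residue templates.

Both directions are exact inverses of each other (to float precision) on
the chi-defining atoms, which is the property the packing model relies on.
Proline's chi2 is treated as a free torsion (ring closure not enforced).
"""

from __future__ import annotations

import numpy as np

from . import residues
from .records import ChiSet, StructureRecord
from .residues import (
    ATOM14,
    CBETA_ANGLE,
    CBETA_BOND,
    CBETA_DIHEDRAL,
    MAX_CHI,
    TEMPLATES_BY_INDEX,
)
from .torus import wrap

__all__ = [
    "dihedral",
    "nerf_place",
    "idealize_cbeta",
    "measure_chi",
    "measure_chi_all",
    "build_atoms",
    "reduce_symmetry",
]

_DEGENERACY_EPS = 1e-8


def dihedral(p1, p2, p3, p4):
    """Signed torsion angle of four points, IUPAC convention (cis = 0).

    Accepts arrays broadcastable to (..., 3); returns radians in (-pi, pi].
    Raises on degenerate geometry (coincident consecutive points or three
    collinear points, which leave the torsion undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    n1 = np.linalg.norm(b1, axis=-1, keepdims=True)
    if np.any(n1 < _DEGENERACY_EPS):
        raise ValueError("degenerate dihedral: coincident central atoms")
    b1u = b1 / n1
    v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
    w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
    if np.any(np.linalg.norm(v, axis=-1) < _DEGENERACY_EPS) or np.any(
        np.linalg.norm(w, axis=-1) < _DEGENERACY_EPS
    ):
        raise ValueError("degenerate dihedral: collinear atoms")
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1u, v) * w, axis=-1)
    ang = np.arctan2(y, x)
    return np.where(ang == -np.pi, np.pi, ang)


def _dihedral_masked(p1, p2, p3, p4):
    """Dihedral that returns 0 (not an error) on degenerate rows, plus a
    validity mask; used for bulk measurement over possibly-missing atoms."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0, b1, b2 = p1 - p2, p3 - p2, p4 - p3
    n1 = np.linalg.norm(b1, axis=-1, keepdims=True)
    ok = (n1[..., 0] > _DEGENERACY_EPS)
    b1u = np.where(n1 > _DEGENERACY_EPS, b1 / np.where(n1 == 0, 1.0, n1), 0.0)
    v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
    w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
    ok &= np.linalg.norm(v, axis=-1) > _DEGENERACY_EPS
    ok &= np.linalg.norm(w, axis=-1) > _DEGENERACY_EPS
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1u, v) * w, axis=-1)
    ang = np.arctan2(y, x)
    return np.where(ok, ang, 0.0), ok


def nerf_place(a, b, c, bond, angle, torsion):
    """Place atom d from frame atoms (a, b, c) by internal coordinates.

    |c - d| = bond, angle(b, c, d) = angle, dihedral(a, b, c, d) = torsion.
    Vectorized over leading dimensions; equivariant under rigid motions of
    the frame by construction.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bond = np.asarray(bond, dtype=float)[..., None]
    angle = np.asarray(angle, dtype=float)[..., None]
    torsion = np.asarray(torsion, dtype=float)[..., None]

    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    return c + bond * (
        -np.cos(angle) * bc
        + np.sin(angle) * (np.cos(torsion) * m + np.sin(torsion) * n)
    )


def idealize_cbeta(n, ca, c):
    """Ideal C-beta position from the backbone frame (virtual for GLY).

    Fixed tetrahedral construction: bond CA-CB = 1.526 A,
    angle N-CA-CB = 110.4 deg, improper dihedral C-N-CA-CB = -122.5 deg.
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    if not (np.all(np.isfinite(n)) and np.all(np.isfinite(ca)) and np.all(np.isfinite(c))):
        raise ValueError("non-finite backbone coordinates")
    cross = np.cross(ca - n, c - ca)
    if np.any(np.linalg.norm(cross, axis=-1) < _DEGENERACY_EPS):
        raise ValueError("collinear backbone: C-beta frame undefined")
    return nerf_place(c, n, ca, CBETA_BOND, CBETA_ANGLE, CBETA_DIHEDRAL)


def build_atoms(backbone, aatype, chi_angles=None):
    """Reconstruct idealized atom14 coordinates from backbone + chi.

    Parameters
    ----------
    backbone : (R, 4, 3) N/CA/C/O coordinates (O is copied through).
    aatype : (R,) residue type indices (unknown residues get backbone only).
    chi_angles : (R, 4) radians or None (all zeros).

    Returns
    -------
    atom14 : (R, 14, 3); mask : (R, 14) bool.

    Bond lengths and angles are template-ideal; chi rotations are applied
    implicitly in build order (chi1 before chi2, ...), so rotating chi_k
    moves exactly the template's rotating set for chi_k.
    """
    backbone = np.asarray(backbone, dtype=float)
    aatype = np.asarray(aatype, dtype=int)
    R = aatype.shape[0]
    if backbone.shape != (R, 4, 3):
        raise ValueError(f"backbone must be (R, 4, 3), got {backbone.shape}")
    if chi_angles is None:
        chi_angles = np.zeros((R, MAX_CHI))
    chi_angles = np.asarray(chi_angles, dtype=float)

    known = aatype < len(residues.AA3)
    if np.any(~np.isfinite(backbone[known][:, :3])):
        raise ValueError("non-finite backbone coordinates")

    atom14 = np.zeros((R, ATOM14, 3))
    mask = np.zeros((R, ATOM14), dtype=bool)
    atom14[:, :4] = backbone
    mask[:, :4] = True

    cb = idealize_cbeta(backbone[:, 0], backbone[:, 1], backbone[:, 2])

    for ti in np.unique(aatype):
        idx = np.nonzero(aatype == ti)[0]
        if ti >= len(residues.AA3):
            continue
        tmpl = TEMPLATES_BY_INDEX[ti]
        if tmpl.name != "GLY":
            atom14[idx, 4] = cb[idx]
            mask[idx, 4] = True
        coords = atom14[idx]
        for rec in tmpl.sidechain:
            p3 = coords[:, rec.frame[0]]
            p2 = coords[:, rec.frame[1]]
            p1 = coords[:, rec.frame[2]]
            if rec.kind == "fixed":
                torsion = np.full(len(idx), rec.offset)
            else:
                torsion = chi_angles[idx, rec.chi_index] + rec.offset
            coords[:, rec.slot] = nerf_place(p3, p2, p1, rec.bond, rec.angle, torsion)
            mask[idx, rec.slot] = True
        atom14[idx] = coords

    return atom14, mask


def measure_chi(structure: StructureRecord, residue_index: int):
    """Chi angles of one residue: (4,) radians and (4,) validity mask.

    An angle is masked out when the residue type lacks it or any of its
    four defining atoms is absent from ``atom_mask``.
    """
    chiset = measure_chi_all(structure)
    return chiset.angles[residue_index], chiset.exists[residue_index]


def measure_chi_all(structure: StructureRecord, symmetry_enabled=True) -> ChiSet:
    """Measure every chi angle of a structure from its atom14 coordinates.

    Returns angles in the full (-pi, pi] chart; apply
    :func:`reduce_symmetry` to move pi-symmetric angles into [0, pi).
    """
    aatype = structure.aatype
    R = aatype.shape[0]
    chi = np.zeros((R, MAX_CHI))
    exists = np.zeros((R, MAX_CHI), dtype=bool)

    for ti in np.unique(aatype):
        if ti >= len(residues.AA3):
            continue
        tmpl = TEMPLATES_BY_INDEX[ti]
        if tmpl.num_chi == 0:
            continue
        idx = np.nonzero(aatype == ti)[0]
        coords = structure.atom14[idx]
        amask = structure.atom_mask[idx]
        for k in range(tmpl.num_chi):
            slots = tmpl.chi_atom_slots[k]
            pts = coords[:, slots]  # (n, 4, 3)
            have = amask[:, slots].all(axis=1)
            ang, ok = _dihedral_masked(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
            chi[idx, k] = np.where(have & ok, ang, 0.0)
            exists[idx, k] = have & ok

    sym = residues.chi_symmetry_mask(aatype, enabled=symmetry_enabled)
    return ChiSet(chi * exists, exists, sym)


def reduce_symmetry(chiset: ChiSet) -> ChiSet:
    """Canonicalize: pi-symmetric angles into [0, pi), others into [-pi, pi).

    For a flagged chi, conformations chi and chi + pi describe the same
    heavy-atom set up to a terminal atom-name swap, so the state space is
    the half circle.
    """
    period = chiset.periods
    out = chiset.copy()
    out.angles = wrap(chiset.angles, period) * chiset.exists
    return out
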