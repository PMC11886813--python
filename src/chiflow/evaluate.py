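"""Side-chain packing metrics.

Reports the standard rotamer-recovery suite: per-chi angular MAE (minimum
arc on the circle, degrees), per-chi accuracy at a 20-degree threshold,
per-residue side-chain heavy-atom RMSD without superposition (the backbone
frame is shared), RMSD split by burial class — core residues have >= 20
C-beta atoms within 10 A, surface residues <= 15 — and a steric clash
count.  Chemically symmetric terminal pairs (ASP OD1/OD2, GLU OE1/OE2,
PHE/TYR ring CD/CE pairs) are matched to minimize RMSD, and pi-symmetric
chi angles are compared with period pi.

MAE/accuracy aggregation is a micro-average over all residues of all
evaluated structures; a per-structure macro-average is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import residues
from .featurize import cbeta_coords
from .kinematics import measure_chi_all, reduce_symmetry
from .records import ChiSet, StructureRecord
from .torus import TWO_PI

__all__ = [
    "angle_error",
    "angle_accuracy",
    "residue_rmsd",
    "per_residue_sidechain_rmsd",
    "classify_core_surface",
    "count_clashes",
    "PackingReport",
    "evaluate_structure",
    "aggregate_reports",
]

ACCURACY_THRESHOLD_DEG = 20.0
CORE_MIN_NEIGHBORS = 20
SURFACE_MAX_NEIGHBORS = 15
NEIGHBOR_RADIUS = 10.0

#: van der Waals radii by element (Angstrom), Rosetta-style clash criterion
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
CLASH_OVERLAP = 0.4  # tolerated overlap subtracted from the radius sum

#: side-chain terminal pairs indistinguishable under a 180-degree flip
SYMMETRIC_PAIRS = {
    "ASP": [("OD1", "OD2")],
    "GLU": [("OE1", "OE2")],
    "PHE": [("CD1", "CD2"), ("CE1", "CE2")],
    "TYR": [("CD1", "CD2"), ("CE1", "CE2")],
}
#: optional amide/guanidinium flips, off by default
EXTENDED_SYMMETRIC_PAIRS = {
    "ASN": [("OD1", "ND2")],
    "GLN": [("OE1", "NE2")],
    "HIS": [("ND1", "CD2"), ("CE1", "NE2")],
    "ARG": [("NH1", "NH2")],
}


def angle_error(pred, ref, symmetric=False):
    """Minimum wrapped absolute difference on the circle, in degrees.

    Symmetric angles are compared with period pi (error <= 90 deg); all
    others with period 2*pi (error <= 180 deg).  Accepts degrees.
    """
    pred = np.deg2rad(np.asarray(pred, dtype=float))
    ref = np.deg2rad(np.asarray(ref, dtype=float))
    period = np.where(np.asarray(symmetric, dtype=bool), np.pi, TWO_PI)
    d = np.abs(pred - ref) % period
    return np.rad2deg(np.minimum(d, period - d))


def _angle_error_rad(pred, ref, period):
    d = np.abs(pred - ref) % period
    return np.minimum(d, period - d)


def angle_accuracy(errors_deg, threshold=ACCURACY_THRESHOLD_DEG):
    """Fraction of angular errors strictly below ``threshold`` degrees.

    Returns NaN for an empty list (reported as absent).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    errors_deg = np.asarray(errors_deg, dtype=float)
    if errors_deg.size == 0:
        return float("nan")
    return float(np.mean(errors_deg < threshold))


def _swap_variants(aa_name, tmpl, extended=False):
    """Atom14 slot permutations generated by symmetric terminal swaps."""
    pairs = list(SYMMETRIC_PAIRS.get(aa_name, []))
    if extended:
        pairs += EXTENDED_SYMMETRIC_PAIRS.get(aa_name, [])
    if not pairs:
        return [np.arange(residues.ATOM14)]
    name_to_slot = {n: i for i, n in enumerate(tmpl.atom14_names)}
    perm = np.arange(residues.ATOM14)
    for a, b in pairs:  # all pairs flip together (one 180-degree rotation)
        ia, ib = name_to_slot[a], name_to_slot[b]
        perm[ia], perm[ib] = ib, ia
    return [np.arange(residues.ATOM14), perm]


def residue_rmsd(pred_atoms, ref_atoms, amino_acid, atom_mask=None, extended_swaps=False):
    """Heavy side-chain RMSD of one residue, no superposition.

    Atoms beyond C-beta (slots 5+) enter; symmetric terminal pairs are
    matched to minimize the RMSD.  Returns NaN for ALA/GLY/unknown (no
    side-chain atoms beyond C-beta).
    """
    tmpl = residues.template_for(amino_acid)
    pred_atoms = np.asarray(pred_atoms, dtype=float)
    ref_atoms = np.asarray(ref_atoms, dtype=float)
    present = tmpl.atom_exists.copy()
    present[:5] = False
    if atom_mask is not None:
        present &= np.asarray(atom_mask, dtype=bool)
    if not present.any():
        return float("nan")
    best = np.inf
    for perm in _swap_variants(tmpl.name, tmpl, extended_swaps):
        d2 = np.sum((pred_atoms[present] - ref_atoms[perm][present]) ** 2, axis=-1)
        best = min(best, float(np.sqrt(np.mean(d2))))
    return best


def per_residue_sidechain_rmsd(pred14, ref14, aatype, atom_mask=None, extended_swaps=False):
    """(R,) RMSD per residue and an (R,) validity mask (False: no side chain)."""
    aatype = np.asarray(aatype)
    R = len(aatype)
    out = np.zeros(R)
    valid = np.zeros(R, dtype=bool)
    for i in range(R):
        if aatype[i] >= len(residues.AA3):
            continue
        m = atom_mask[i] if atom_mask is not None else None
        r = residue_rmsd(pred14[i], ref14[i], int(aatype[i]), atom_mask=m,
                         extended_swaps=extended_swaps)
        if np.isfinite(r):
            out[i] = r
            valid[i] = True
    return out, valid


def classify_core_surface(structure: StructureRecord):
    """Burial labels from idealized C-beta contacts (GLY uses a virtual one).

    count = number of *other* residues' C-beta within 10 A;
    >= 20 -> 'core', <= 15 -> 'surface', otherwise 'other'.
    """
    cb = cbeta_coords(structure)
    tree = cKDTree(cb)
    counts = np.array([len(tree.query_ball_point(p, NEIGHBOR_RADIUS)) - 1 for p in cb])
    labels = np.full(structure.num_residues, "other", dtype=object)
    labels[counts >= CORE_MIN_NEIGHBORS] = "core"
    labels[counts <= SURFACE_MAX_NEIGHBORS] = "surface"
    return labels


#: bonded-path separation up to which atom pairs are exempt from clash
#: counting (3 = exclude 1-2, 1-3 and 1-4 neighbours, the usual convention)
CLASH_EXCLUDE_BOND_SEPARATION = 3

_cross_pair_cache = {}


def _cross_peptide_exclusions(ti, tj):
    """Cross-residue atom14 slot pairs within CLASH_EXCLUDE_BOND_SEPARATION
    bonds of each other across the peptide bond C_i - N_{i+1} (BFS on the
    two-residue bond graph; covers proline's ring closure)."""
    key = (ti, tj)
    if key in _cross_pair_cache:
        return _cross_pair_cache[key]
    adj = {}

    def add(a, b):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    for off, t in ((0, ti), (14, tj)):
        if t < len(residues.AA3):
            for a, b in residues.TEMPLATES_BY_INDEX[t].bonds:
                add(off + a, off + b)
        else:
            add(off + 0, off + 1)
            add(off + 1, off + 2)
            add(off + 2, off + 3)
    add(2, 14 + 0)  # peptide bond C_i - N_{i+1}

    pairs = set()
    for start in list(adj):
        dist = {start: 0}
        frontier = [start]
        for d in range(1, CLASH_EXCLUDE_BOND_SEPARATION + 1):
            nxt = []
            for node in frontier:
                for nb in adj[node]:
                    if nb not in dist:
                        dist[nb] = d
                        nxt.append(nb)
            frontier = nxt
        for node, d in dist.items():
            if start < 14 <= node:
                pairs.add((start, node - 14))
    _cross_pair_cache[key] = frozenset(pairs)
    return _cross_pair_cache[key]


def _excluded_pairs(structure: StructureRecord):
    """Flat atom-index pairs exempt from clash counting: all pairs within
    CLASH_EXCLUDE_BOND_SEPARATION bonds across consecutive same-chain
    residues (same-residue pairs are excluded wholesale elsewhere)."""
    R = structure.num_residues
    excl = set()
    for i in range(R - 1):
        j = i + 1
        if structure.chain_ids[i] != structure.chain_ids[j]:
            continue
        for a, b in _cross_peptide_exclusions(structure.aatype[i], structure.aatype[j]):
            excl.add((i * 14 + a, j * 14 + b))
    return excl


def count_clashes(structure: StructureRecord, atom14=None, atom_mask=None, overlap=CLASH_OVERLAP):
    """Number of clashing non-bonded heavy-atom pairs.

    A pair clashes when its distance is below the sum of van der Waals radii
    minus ``overlap`` (0.4 A default).  Same-residue pairs and 1-2/1-3
    neighbors across the peptide bond are excluded.
    """
    atoms = structure.atom14 if atom14 is None else np.asarray(atom14, dtype=float)
    mask = structure.atom_mask if atom_mask is None else np.asarray(atom_mask, dtype=bool)
    R = structure.num_residues
    flat_idx = np.nonzero(mask.reshape(-1))[0]
    coords = atoms.reshape(-1, 3)[flat_idx]
    res_of = flat_idx // 14

    radii = np.empty(len(flat_idx))
    for n, a in enumerate(flat_idx):
        ri, slot = divmod(a, 14)
        ti = structure.aatype[ri]
        name = (
            residues.TEMPLATES_BY_INDEX[ti].atom14_names[slot]
            if ti < len(residues.AA3)
            else residues.BACKBONE_ATOMS[slot]
        )
        radii[n] = VDW_RADII[name[0]]

    excl = _excluded_pairs(structure)
    tree = cKDTree(coords)
    max_cut = 2 * max(VDW_RADII.values()) - overlap
    count = 0
    for a, b in tree.query_pairs(max_cut):
        ia, ib = flat_idx[a], flat_idx[b]
        if res_of[a] == res_of[b]:
            continue
        if (ia, ib) in excl or (ib, ia) in excl:
            continue
        cutoff = radii[a] + radii[b] - overlap
        if np.linalg.norm(coords[a] - coords[b]) < cutoff:
            count += 1
    return count


@dataclass
class PackingReport:
    """Evaluation summary for one structure (angles in degrees, RMSD in A)."""

    mae_per_chi: list
    accuracy_per_chi: list
    rmsd_all: float
    rmsd_core: float
    rmsd_surface: float
    clash_count: int
    counts_per_chi: list
    per_residue: list = field(default_factory=list)

    def to_json(self, path=None):
        payload = {
            "schema_version": 1,
            "mae_per_chi_deg": self.mae_per_chi,
            "accuracy_per_chi": self.accuracy_per_chi,
            "rmsd_all": self.rmsd_all,
            "rmsd_core": self.rmsd_core,
            "rmsd_surface": self.rmsd_surface,
            "clash_count": self.clash_count,
            "counts_per_chi": self.counts_per_chi,
            "per_residue": self.per_residue,
        }
        text = json.dumps(payload, indent=1)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("chain\tresid\taa\tchi1_err\tchi2_err\tchi3_err\tchi4_err\trmsd\tburial\n")
            for row in self.per_residue:
                errs = "\t".join(
                    f"{e:.2f}" if e is not None else "." for e in row["chi_errors_deg"]
                )
                rmsd = f"{row['rmsd']:.3f}" if row["rmsd"] is not None else "."
                fh.write(
                    f"{row['chain']}\t{row['resid']}\t{row['aa']}\t{errs}\t{rmsd}\t{row['burial']}\n"
                )


def _chi_errors(pred_chi: ChiSet, ref_chi: ChiSet):
    """(R, 4) error degrees and (R, 4) comparable mask (min-arc, period-aware)."""
    both = pred_chi.exists & ref_chi.exists
    period = ref_chi.periods
    err = _angle_error_rad(pred_chi.angles, ref_chi.angles, period)
    return np.rad2deg(err) * both, both


def evaluate_structure(
    structure: StructureRecord,
    pred_atom14,
    pred_mask=None,
    ref_atom14=None,
    ref_mask=None,
    per_residue_table=True,
    extended_swaps=False,
) -> PackingReport:
    """Compare predicted side chains to the reference for one structure.

    The reference defaults to ``structure.atom14``.  Chi angles are
    measured from both coordinate sets; residues missing reference angles
    are excluded from (and counted against) the angle metrics.
    """
    ref_atoms = structure.atom14 if ref_atom14 is None else np.asarray(ref_atom14)
    r_mask = structure.atom_mask if ref_mask is None else np.asarray(ref_mask, dtype=bool)
    p_mask = r_mask if pred_mask is None else np.asarray(pred_mask, dtype=bool)

    pred_rec = structure.copy()
    pred_rec.atom14 = np.asarray(pred_atom14, dtype=float)
    pred_rec.atom_mask = p_mask
    ref_rec = structure.copy()
    ref_rec.atom14 = ref_atoms
    ref_rec.atom_mask = r_mask

    pred_chi = reduce_symmetry(measure_chi_all(pred_rec))
    ref_chi = reduce_symmetry(measure_chi_all(ref_rec))
    err_deg, comparable = _chi_errors(pred_chi, ref_chi)

    mae, acc, counts = [], [], []
    for k in range(4):
        sel = comparable[:, k]
        counts.append(int(sel.sum()))
        if sel.any():
            mae.append(float(err_deg[sel, k].mean()))
            acc.append(angle_accuracy(err_deg[sel, k]))
        else:
            mae.append(float("nan"))
            acc.append(float("nan"))

    rmsd, valid = per_residue_sidechain_rmsd(
        pred_rec.atom14, ref_atoms, structure.aatype, p_mask & r_mask,
        extended_swaps=extended_swaps,
    )
    burial = classify_core_surface(structure)
    core = valid & (burial == "core")
    surf = valid & (burial == "surface")

    def _mean(sel):
        return float(rmsd[sel].mean()) if sel.any() else float("nan")

    clashes = count_clashes(pred_rec)

    table = []
    if per_residue_table:
        for i in range(structure.num_residues):
            table.append(
                {
                    "chain": str(structure.chain_ids[i]),
                    "resid": int(structure.residue_numbers[i]),
                    "aa": residues.AA3[structure.aatype[i]]
                    if structure.aatype[i] < 20
                    else "UNK",
                    "chi_errors_deg": [
                        float(err_deg[i, k]) if comparable[i, k] else None for k in range(4)
                    ],
                    "rmsd": float(rmsd[i]) if valid[i] else None,
                    "burial": str(burial[i]),
                }
            )

    return PackingReport(
        mae_per_chi=mae,
        accuracy_per_chi=acc,
        rmsd_all=_mean(valid),
        rmsd_core=_mean(core),
        rmsd_surface=_mean(surf),
        clash_count=clashes,
        counts_per_chi=counts,
        per_residue=table,
    )


def aggregate_reports(reports, macro=False):
    """Combine per-structure reports into dataset-level numbers.

    micro (default): each chi entry counts once across the whole dataset;
    macro: unweighted mean of per-structure values.
    """
    mae = np.full(4, np.nan)
    acc = np.full(4, np.nan)
    for k in range(4):
        if macro:
            vals = [r.mae_per_chi[k] for r in reports if np.isfinite(r.mae_per_chi[k])]
            accs = [r.accuracy_per_chi[k] for r in reports if np.isfinite(r.accuracy_per_chi[k])]
            if vals:
                mae[k] = float(np.mean(vals))
                acc[k] = float(np.mean(accs))
        else:
            n = sum(r.counts_per_chi[k] for r in reports)
            if n:
                mae[k] = sum(
                    r.mae_per_chi[k] * r.counts_per_chi[k]
                    for r in reports
                    if r.counts_per_chi[k]
                ) / n
                acc[k] = sum(
                    r.accuracy_per_chi[k] * r.counts_per_chi[k]
                    for r in reports
                    if r.counts_per_chi[k]
                ) / n
    return {
        "mae_per_chi_deg": mae.tolist(),
        "accuracy_per_chi": acc.tolist(),
        "rmsd_all": float(np.nanmean([r.rmsd_all for r in reports])),
        "rmsd_core": float(np.nanmean([r.rmsd_core for r in reports]))
        if any(np.isfinite(r.rmsd_core) for r in reports)
        else float("nan"),
        "rmsd_surface": float(np.nanmean([r.rmsd_surface for r in reports]))
        if any(np.isfinite(r.rmsd_surface) for r in reports)
        else float("nan"),
        "clash_count_mean": float(np.mean([r.clash_count for r in reports])),
    }
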