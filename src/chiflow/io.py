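"""Reading/writing PDB and mmCIF structures and dataset filtering.

Parsing and serialization go through gemmi; this module maps between
gemmi's hierarchy and the atom14 :class:`~chiflow.records.StructureRecord`.
Only the first model is read; alternate locations are resolved by highest
occupancy (label order breaks ties); hydrogens, OXT and non-polymer
residues are dropped.  Unknown polymer residues are kept with the extra
one-hot class and an empty chi mask.

Dataset filters follow the curation used for training-set construction:
residues with missing backbone atoms or overlapping alpha carbons are
removed, then structures with more than 25% unknown residues or fewer than
40 residues are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from . import residues
from .records import StructureRecord

__all__ = ["DatasetFilterConfig", "read_structure", "write_structure", "apply_filters", "read_manifest"]


@dataclass
class DatasetFilterConfig:
    min_residues: int = 40
    max_unknown_fraction: float = 0.25
    ca_clash_tolerance: float = 1e-3  # Angstrom


_BACKBONE_SET = set(residues.BACKBONE_ATOMS)
# one PDB chain-id column: 26 letters x2 + 10 digits
_PDB_MAX_CHAINS = 62


def _pick_altloc(atoms):
    """Highest occupancy wins; ties resolve to the earliest altloc label."""
    return max(atoms, key=lambda a: (a.occ, -ord(a.altloc or " ")))


def read_structure(path, format=None) -> StructureRecord:
    """Parse a PDB/mmCIF file into a StructureRecord (first model only)."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    st.setup_entities()
    model = st[0]

    aatype, chains, numbers, icodes = [], [], [], []
    coords, masks = [], []
    for chain in model:
        rows = []
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = res.name in residues.AA3 or (info is not None and info.is_amino_acid())
            if not is_aa:
                continue
            ti = residues.AA3_TO_INDEX.get(res.name, residues.UNK_INDEX)
            tmpl = residues.TEMPLATES_BY_INDEX[ti] if ti < 20 else None
            names = tmpl.atom14_names if tmpl else tuple(residues.BACKBONE_ATOMS)
            slot_of = {n: i for i, n in enumerate(names)}
            xyz = np.zeros((residues.ATOM14, 3))
            m = np.zeros(residues.ATOM14, dtype=bool)
            by_name = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            for name, copies in by_name.items():
                slot = slot_of.get(name)
                if slot is None:
                    continue
                a = _pick_altloc(copies)
                xyz[slot] = [a.pos.x, a.pos.y, a.pos.z]
                m[slot] = True
            rows.append((ti, res.seqid.num, res.seqid.icode.strip(), xyz, m))
        if not rows:
            warnings.warn(f"{path}: chain {chain.name} has no polymer residues; skipped")
            continue
        for ti, num, icode, xyz, m in rows:
            aatype.append(ti)
            chains.append(chain.name)
            numbers.append(num)
            icodes.append(icode)
            coords.append(xyz)
            masks.append(m)

    if not aatype:
        raise ValueError(f"{path}: no protein residues found")
    coords = np.array(coords)
    masks = np.array(masks)
    return StructureRecord(
        aatype=np.array(aatype),
        chain_ids=np.array(chains),
        backbone=coords[:, :4].copy(),
        atom14=coords,
        atom_mask=masks,
        residue_numbers=np.array(numbers),
        insertion_codes=np.array(icodes, dtype=object),
        name=Path(path).stem,
    )


def write_structure(record: StructureRecord, path, format=None, bfactor=None):
    """Write a StructureRecord as PDB or mmCIF (by extension or ``format``).

    ``bfactor`` is an optional per-residue scalar (e.g. predicted RMSD)
    stored in the B-factor column.  Structures with more chains than a PDB
    file can hold fall back to mmCIF with a warning.
    """
    path = Path(path)
    fmt = (format or ("cif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb")).lower()
    n_chains = len(set(map(str, record.chain_ids)))
    if fmt == "pdb" and n_chains > _PDB_MAX_CHAINS:
        warnings.warn(f"{n_chains} chains exceed the PDB format; writing mmCIF instead")
        fmt = "cif"
        path = path.with_suffix(".cif")

    st = gemmi.Structure()
    st.name = record.name or "chiflow"
    model = gemmi.Model("1")
    chain_obj = {}
    for i in range(record.num_residues):
        cid = str(record.chain_ids[i])
        if cid not in chain_obj:
            chain_obj[cid] = gemmi.Chain(cid)
            model.add_chain(chain_obj[cid])
        chain = model[cid]
        ti = record.aatype[i]
        names = (
            residues.TEMPLATES_BY_INDEX[ti].atom14_names
            if ti < 20
            else tuple(residues.BACKBONE_ATOMS)
        )
        res = gemmi.Residue()
        res.name = residues.AA3[ti] if ti < 20 else "UNK"
        res.seqid = gemmi.SeqId(int(record.residue_numbers[i]), str(record.insertion_codes[i]) or " ")
        for slot, name in enumerate(names):
            if not record.atom_mask[i, slot]:
                continue
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            x, y, z = record.atom14[i, slot]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            atom.occ = 1.0
            atom.b_iso = float(bfactor[i]) if bfactor is not None else 0.0
            res.add_atom(atom)
        chain.add_residue(res)
    st.add_model(model)
    st.setup_entities()

    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
    return path


def apply_filters(record: StructureRecord, config: DatasetFilterConfig = DatasetFilterConfig()):
    """Apply dataset curation filters.

    Removes residues lacking any of N/CA/C (or with non-finite backbone),
    then removes the later residue of any alpha-carbon pair closer than the
    tolerance.  Returns ``(filtered_record, reason)``: the record is None
    when the structure is rejected (too short, or too many unknowns) and
    ``reason`` says why.  Idempotent.
    """
    m = record.atom_mask[:, :3].all(axis=1) & np.isfinite(record.backbone[:, :3]).all(
        axis=(1, 2)
    )
    idx = np.nonzero(m)[0]

    kept = []
    kept_ca = []
    tol = config.ca_clash_tolerance
    for i in idx:  # earlier residue wins an overlap
        ca = record.backbone[i, 1]
        if kept_ca and np.min(np.linalg.norm(np.array(kept_ca) - ca, axis=1)) < tol:
            continue
        kept.append(i)
        kept_ca.append(ca)
    kept = np.array(kept, dtype=int)

    if len(kept) == 0:
        return None, "no residues with complete backbone"
    filtered = record.subset(kept)
    unknown_frac = float(np.mean(filtered.aatype >= 20))
    if unknown_frac > config.max_unknown_fraction:
        return None, f"unknown residue fraction {unknown_frac:.2f} > {config.max_unknown_fraction}"
    if filtered.num_residues < config.min_residues:
        return None, f"{filtered.num_residues} residues < {config.min_residues}"
    return filtered, "ok"


def read_manifest(path):
    """Plain-text dataset list: one structure path per line, '#' comments."""
    base = Path(path).parent
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        p = Path(line)
        out.append(p if p.is_absolute() else base / p)
    return out
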