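"""Dihedral measurement, idealized reconstruction, and symmetry handling."""

import numpy as np
import pytest

from chiflow import residues
from chiflow.kinematics import (
    build_atoms,
    dihedral,
    idealize_cbeta,
    measure_chi,
    measure_chi_all,
    reduce_symmetry,
)
from chiflow.records import ChiSet, StructureRecord
from chiflow.torus import log_map

from conftest import apply_rigid, rigid_transform


def _single_residue_backbone():
    n = np.array([1.458, 0.0, 0.0])
    ca = np.zeros(3)
    ang = np.pi - np.deg2rad(111.0)
    c = ca + 1.525 * np.array([np.cos(ang), np.sin(ang), 0.0])
    o = c + np.array([0.4, 1.1, 0.2])
    return np.stack([n, ca, c, o])[None]


def _record_for(aa, chi):
    tmpl = residues.template_for(aa)
    bb = _single_residue_backbone()
    atoms, mask = build_atoms(bb, np.array([tmpl.index]), np.asarray(chi)[None])
    return StructureRecord(
        aatype=[tmpl.index], chain_ids=["A"], backbone=bb, atom14=atoms, atom_mask=mask
    )


def oracle_dihedral(p1, p2, p3, p4):
    """Independent normal-vector formula for the signed torsion (cis = 0)."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    y = np.cross(n1, n2) @ (b2 / np.linalg.norm(b2))
    x = n1 @ n2
    return np.arctan2(y, x)


class TestDihedral:
    def test_planar_trans_and_cis(self):
        p1 = np.array([1.0, 1.0, 0.0])
        p2 = np.array([0.0, 1.0, 0.0])
        p3 = np.array([0.0, 0.0, 0.0])
        trans = np.array([1.0, -1.0, 0.0]) * -1 + np.array([0, -0, 0])  # opposite side
        assert dihedral(p1, p2, p3, np.array([-1.0, -1.0, 0.0])) == pytest.approx(np.pi)
        assert dihedral(p1, p2, p3, np.array([1.0, -1.0, 0.0])) == pytest.approx(0.0)

    def test_against_independent_formula(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            pts = rng.normal(size=(4, 3)) * 3
            try:
                got = dihedral(*pts)
            except ValueError:
                continue
            assert got == pytest.approx(oracle_dihedral(*pts), abs=1e-9)

    def test_degenerate_geometry_raises(self):
        p = np.zeros(3)
        with pytest.raises(ValueError):
            dihedral(p, p, np.array([1.0, 0, 0]), np.array([1.0, 1.0, 0]))
        with pytest.raises(ValueError):
            # p1 collinear with the central bond
            dihedral(
                np.array([-1.0, 0, 0]),
                np.zeros(3),
                np.array([1.0, 0, 0]),
                np.array([2.0, 1.0, 0]),
            )


class TestMeasureChi:
    def test_ala_has_no_chi(self):
        rec = _record_for("ALA", np.zeros(4))
        ang, mask = measure_chi(rec, 0)
        assert not mask.any()

    def test_missing_atom_masks_chi(self):
        rec = _record_for("SER", np.array([1.0, 0, 0, 0]))
        og = residues.template_for("SER").atom14_names.index("OG")
        rec.atom_mask[0, og] = False
        ang, mask = measure_chi(rec, 0)
        assert not mask[0]

    def test_unknown_residue_has_no_chi(self):
        rec = _record_for("GLY", np.zeros(4))
        rec.aatype[:] = residues.UNK_INDEX
        chis = measure_chi_all(rec)
        assert not chis.exists.any()


class TestBuildAtoms:
    def test_gly_backbone_only(self):
        bb = _single_residue_backbone()
        atoms, mask = build_atoms(bb, np.array([residues.AA3_TO_INDEX["GLY"]]), np.zeros((1, 4)))
        assert mask[0].sum() == 4
        assert np.allclose(atoms[0, :4], bb[0])

    @pytest.mark.parametrize("aa", residues.CHI_BEARING)
    def test_roundtrip_all_chi_bearing(self, aa):
        """build_atoms -> measure_chi recovers chi to < 1e-6 rad, 100 draws."""
        rng = np.random.default_rng(hash(aa) % 2**31)
        tmpl = residues.template_for(aa)
        for _ in range(100):
            chi = rng.uniform(-np.pi, np.pi, 4)
            rec = _record_for(aa, chi)
            chis = measure_chi_all(rec)
            assert np.array_equal(chis.exists[0], tmpl.chi_mask)
            err = np.abs(log_map(chis.angles[0], chi))[tmpl.chi_mask]
            assert err.max() < 1e-6

    def test_chi_rotation_moves_exactly_the_rotating_set(self):
        rng = np.random.default_rng(5)
        for aa in ("ARG", "LEU", "TRP", "THR"):
            tmpl = residues.template_for(aa)
            chi = rng.uniform(-np.pi, np.pi, 4)
            base, _ = build_atoms(
                _single_residue_backbone(), np.array([tmpl.index]), chi[None]
            )
            for k in range(tmpl.num_chi):
                bumped = chi.copy()
                bumped[k] += 0.37
                moved_atoms, _ = build_atoms(
                    _single_residue_backbone(), np.array([tmpl.index]), bumped[None]
                )
                disp = np.linalg.norm(moved_atoms[0] - base[0], axis=1)
                moving = tmpl.rotating_masks[k] & tmpl.atom_exists
                static = ~tmpl.rotating_masks[k] & tmpl.atom_exists
                assert disp[moving].min() > 1e-4
                assert disp[static].max() < 1e-9

    def test_equivariance_under_rigid_motion(self, mini_protein):
        rec, chis = mini_protein
        rng = np.random.default_rng(3)
        R, t = rigid_transform(rng)
        moved = apply_rigid(rec, R, t)
        atoms, mask = build_atoms(rec.backbone, rec.aatype, chis.angles)
        atoms_m, _ = build_atoms(moved.backbone, moved.aatype, chis.angles)
        assert np.abs(atoms_m[mask] - (atoms[mask] @ R.T + t)).max() < 1e-6

    def test_bonded_distances_match_template_ideals(self, mini_protein):
        rec, chis = mini_protein
        atoms, mask = build_atoms(rec.backbone, rec.aatype, chis.angles)
        for i in range(rec.num_residues):
            tmpl = residues.TEMPLATES_BY_INDEX[rec.aatype[i]]
            for srec in tmpl.sidechain:
                d = np.linalg.norm(atoms[i, srec.slot] - atoms[i, srec.frame[2]])
                assert abs(d - srec.bond) < 0.01

    def test_nonfinite_backbone_rejected(self):
        bb = _single_residue_backbone().copy()
        bb[0, 1] = np.nan
        with pytest.raises(ValueError):
            build_atoms(bb, np.array([residues.AA3_TO_INDEX["SER"]]), np.zeros((1, 4)))


class TestIdealizeCbeta:
    def test_bond_length_in_ideal_range(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n, ca, c = rng.normal(size=(3, 3)) * 2
            if np.linalg.norm(np.cross(ca - n, c - ca)) < 1e-3:
                continue
            cb = idealize_cbeta(n, ca, c)
            assert 1.52 <= np.linalg.norm(cb - ca) <= 1.54

    def test_rigid_equivariance(self):
        rng = np.random.default_rng(6)
        n, ca, c = rng.normal(size=(3, 3)) * 3
        R, t = rigid_transform(rng)
        cb = idealize_cbeta(n, ca, c)
        cb2 = idealize_cbeta(n @ R.T + t, ca @ R.T + t, c @ R.T + t)
        assert np.abs(cb2 - (cb @ R.T + t)).max() < 1e-9

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            idealize_cbeta(np.zeros(3), np.array([1.0, 0, 0]), np.array([2.0, 0, 0]))


class TestSymmetry:
    def test_reduce_maps_flagged_angles_to_half_circle(self):
        asp = residues.template_for("ASP")
        chis = ChiSet(
            np.array([[0.2, np.deg2rad(190.0), 0.0, 0.0]]),
            asp.chi_mask[None].copy(),
            asp.chi_symmetric[None].copy(),
        )
        red = reduce_symmetry(chis)
        assert red.angles[0, 1] == pytest.approx(np.deg2rad(10.0))
        assert red.angles[0, 0] == pytest.approx(0.2)  # chi1 untouched

    def test_leu_chi2_not_flagged(self):
        leu = residues.template_for("LEU")
        assert not leu.chi_symmetric.any()

    def test_flip_produces_identical_atom_set(self):
        """For a pi-symmetric chi, chi and chi+pi give the same heavy atoms
        up to an atom-name swap (assignment-matching oracle)."""
        rng = np.random.default_rng(9)
        for aa, k in (("ASP", 1), ("GLU", 2), ("PHE", 1), ("TYR", 1)):
            tmpl = residues.template_for(aa)
            assert tmpl.chi_symmetric[k]
            chi = rng.uniform(-np.pi, np.pi, 4)
            flipped = chi.copy()
            flipped[k] += np.pi
            a, m = build_atoms(_single_residue_backbone(), np.array([tmpl.index]), chi[None])
            b, _ = build_atoms(
                _single_residue_backbone(), np.array([tmpl.index]), flipped[None]
            )
            pa, pb = a[0][m[0]], b[0][m[0]]
            # greedy nearest-neighbour assignment between the two atom sets
            d = np.linalg.norm(pa[:, None] - pb[None, :], axis=-1)
            assert d.min(axis=1).max() < 1e-6
            assert d.min(axis=0).max() < 1e-6
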