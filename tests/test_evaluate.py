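"""Metric suite: angular errors, RMSD, burial classes, clash counting."""

import numpy as np
import pytest

from chiflow import residues
from chiflow.evaluate import (
    angle_accuracy,
    angle_error,
    classify_core_surface,
    count_clashes,
    evaluate_structure,
    per_residue_sidechain_rmsd,
    residue_rmsd,
    VDW_RADII,
    CLASH_OVERLAP,
)
from chiflow.kinematics import build_atoms
from chiflow.records import StructureRecord

from conftest import apply_rigid, rigid_transform


class TestAngleError:
    def test_wraps_across_zero(self):
        assert angle_error(350.0, 10.0) == pytest.approx(20.0)
        assert angle_error(10.0, 350.0) == pytest.approx(20.0)  # symmetric in args

    def test_identical_angles(self):
        assert angle_error(123.4, 123.4) == pytest.approx(0.0)

    def test_pi_symmetric_comparison(self):
        # ASP chi2: 175 vs 355 differ by exactly 180 -> same state
        assert angle_error(175.0, 355.0, symmetric=True) == pytest.approx(0.0)
        assert angle_error(175.0, 355.0, symmetric=False) == pytest.approx(180.0)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        p, r = rng.uniform(0, 720, (2, 500))
        assert np.all(angle_error(p, r) <= 180.0)
        assert np.all(angle_error(p, r, symmetric=True) <= 90.0)


class TestAngleAccuracy:
    def test_examples(self):
        assert angle_accuracy([0.0, 0.0, 0.0]) == 1.0
        assert angle_accuracy([10.0, 30.0]) == 0.5
        assert np.isnan(angle_accuracy([]))

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(1)
        errs = rng.uniform(0, 90, 300)
        expected = sum(1 for e in errs if e < 20.0) / len(errs)
        assert angle_accuracy(errs) == pytest.approx(expected)

    def test_strict_threshold(self):
        assert angle_accuracy([20.0]) == 0.0  # boundary excluded

    def test_positive_threshold_required(self):
        with pytest.raises(ValueError):
            angle_accuracy([1.0], threshold=0)


class TestResidueRmsd:
    def _arg_atoms(self, chi):
        tmpl = residues.template_for("ARG")
        bb = np.array([[[1.458, 0, 0], [0, 0, 0], [-0.55, 1.42, 0], [0, 2.4, 0.2]]])
        atoms, mask = build_atoms(bb, np.array([tmpl.index]), np.asarray(chi)[None])
        return atoms[0], mask[0]

    def test_identical_atoms_zero(self):
        a, m = self._arg_atoms([0.5, 1.0, -0.5, 2.0])
        assert residue_rmsd(a, a, "ARG", m) == 0.0

    def test_single_displaced_atom_formula(self):
        a, m = self._arg_atoms([0.5, 1.0, -0.5, 2.0])
        b = a.copy()
        nz = residues.template_for("ARG").atom14_names.index("NZ") if False else 10
        # displace the last side-chain atom (NH2, slot 10) by 1 A
        b[10] += np.array([1.0, 0.0, 0.0])
        n = int(m[5:].sum())  # side-chain atoms beyond CB
        assert residue_rmsd(b, a, "ARG", m) == pytest.approx(1.0 / np.sqrt(n))

    def test_symmetric_swap_invariance(self):
        """Exchanging OD1/OD2 in the reference leaves the RMSD unchanged."""
        tmpl = residues.template_for("ASP")
        bb = np.array([[[1.458, 0, 0], [0, 0, 0], [-0.55, 1.42, 0], [0, 2.4, 0.2]]])
        a, m = build_atoms(bb, np.array([tmpl.index]), np.array([[0.4, 0.9, 0, 0]]))
        b, _ = build_atoms(bb, np.array([tmpl.index]), np.array([[0.7, 1.6, 0, 0]]))
        i1 = tmpl.atom14_names.index("OD1")
        i2 = tmpl.atom14_names.index("OD2")
        swapped = b[0].copy()
        swapped[[i1, i2]] = swapped[[i2, i1]]
        r1 = residue_rmsd(a[0], b[0], "ASP", m[0])
        r2 = residue_rmsd(a[0], swapped, "ASP", m[0])
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_ala_gly_excluded(self, mini_protein):
        rec, chis = mini_protein
        rmsd, valid = per_residue_sidechain_rmsd(rec.atom14, rec.atom14, rec.aatype, rec.atom_mask)
        for aa in ("ALA", "GLY"):
            ti = residues.AA3_TO_INDEX[aa]
            assert not valid[rec.aatype == ti].any()


class TestCoreSurface:
    def test_isolated_pair_is_surface(self):
        bb = np.zeros((2, 4, 3))
        bb[0] = [[1.458, 0, 0], [0, 0, 0], [-0.55, 1.42, 0], [0, 2.4, 0]]
        bb[1] = bb[0] + np.array([30.0, 0, 0])
        rec = StructureRecord(
            aatype=[0, 0], chain_ids=["A", "A"], backbone=bb,
            atom14=np.zeros((2, 14, 3)), atom_mask=np.zeros((2, 14), bool),
        )
        assert list(classify_core_surface(rec)) == ["surface", "surface"]

    def test_dense_cluster_is_core(self):
        rng = np.random.default_rng(2)
        R = 25
        bb = np.zeros((R, 4, 3))
        centers = rng.uniform(-3.5, 3.5, size=(R, 3))  # all within a 10 A ball
        frame = np.array([[1.458, 0, 0], [0, 0, 0], [-0.55, 1.42, 0], [0, 2.4, 0]])
        bb[:] = frame
        bb += centers[:, None, :]
        rec = StructureRecord(
            aatype=[0] * R, chain_ids=["A"] * R, backbone=bb,
            atom14=np.zeros((R, 14, 3)), atom_mask=np.zeros((R, 14), bool),
        )
        assert np.all(classify_core_surface(rec) == "core")

    def test_matches_brute_force_counts(self, mini_dataset):
        from chiflow.featurize import cbeta_coords

        for rec, _ in mini_dataset:
            cb = cbeta_coords(rec)
            labels = classify_core_surface(rec)
            d = np.linalg.norm(cb[:, None] - cb[None, :], axis=-1)
            counts = (d <= 10.0).sum(axis=1) - 1
            expect = np.where(counts >= 20, "core", np.where(counts <= 15, "surface", "other"))
            assert np.array_equal(labels.astype(str), expect)

    def test_labels_independent_of_side_chains(self, mini_protein):
        rec, chis = mini_protein
        bare = rec.copy()
        bare.atom14 = np.zeros_like(rec.atom14)
        assert np.array_equal(classify_core_surface(rec), classify_core_surface(bare))


def _two_atom_record(distance):
    bb = np.zeros((2, 4, 3))
    bb[0] = [[1.458, 0, 0], [0, 0, 0], [-0.55, 1.42, 0], [30, 30, 30]]
    bb[1] = bb[0] + np.array([distance, 17.0, 0.0])
    rec = StructureRecord(
        aatype=[residues.AA3_TO_INDEX["GLY"]] * 2,
        chain_ids=["A", "B"],
        backbone=bb,
        atom14=np.zeros((2, 14, 3)),
        atom_mask=np.zeros((2, 14), bool),
    )
    # keep a single CA atom per residue
    rec.atom14[0, 1] = [0.0, 0.0, 0.0]
    rec.atom14[1, 1] = [distance, 0.0, 0.0]
    rec.atom_mask[:, 1] = True
    return rec


class TestClashes:
    def test_distant_atoms_no_clash(self):
        assert count_clashes(_two_atom_record(10.0)) == 0

    def test_two_close_carbons_clash(self):
        # CA-CA: vdW sum 3.4, threshold 3.0 -> 2.0 A is a clash
        assert count_clashes(_two_atom_record(2.0)) == 1
        assert count_clashes(_two_atom_record(3.1)) == 0

    def test_matches_brute_force_oracle(self, mini_dataset):
        from chiflow.evaluate import _excluded_pairs

        for rec, _ in mini_dataset:
            got = count_clashes(rec)
            # O(n^2) reference scan (shares only the exclusion *policy*)
            excl_pairs = _excluded_pairs(rec)
            flat = np.nonzero(rec.atom_mask.reshape(-1))[0]
            coords = rec.atom14.reshape(-1, 3)
            n = 0
            for ii in range(len(flat)):
                for jj in range(ii + 1, len(flat)):
                    a, b = flat[ii], flat[jj]
                    if a // 14 == b // 14:
                        continue
                    if (a, b) in excl_pairs or (b, a) in excl_pairs:
                        continue
                    na = residues.TEMPLATES_BY_INDEX[rec.aatype[a // 14]].atom14_names[a % 14]
                    nb = residues.TEMPLATES_BY_INDEX[rec.aatype[b // 14]].atom14_names[b % 14]
                    cut = VDW_RADII[na[0]] + VDW_RADII[nb[0]] - CLASH_OVERLAP
                    if np.linalg.norm(coords[a] - coords[b]) < cut:
                        n += 1
            assert got == n


class TestEvaluateStructure:
    def test_self_evaluation_is_perfect(self, mini_protein):
        rec, chis = mini_protein
        rep = evaluate_structure(rec, rec.atom14, rec.atom_mask, per_residue_table=False)
        for k in range(4):
            if rep.counts_per_chi[k]:
                assert rep.mae_per_chi[k] == pytest.approx(0.0, abs=1e-9)
                assert rep.accuracy_per_chi[k] == 1.0
        assert rep.rmsd_all == pytest.approx(0.0, abs=1e-12)

    def test_rigid_invariance_of_metrics(self, mini_protein):
        rec, chis = mini_protein
        rng = np.random.default_rng(5)
        R, t = rigid_transform(rng)
        pred, mask = build_atoms(rec.backbone, rec.aatype, chis.angles * 0.9)
        rep1 = evaluate_structure(rec, pred, mask, per_residue_table=False)
        moved = apply_rigid(rec, R, t)
        pred_m = pred @ R.T + t
        rep2 = evaluate_structure(moved, pred_m, mask, per_residue_table=False)
        assert np.allclose(
            np.nan_to_num(rep1.mae_per_chi), np.nan_to_num(rep2.mae_per_chi), atol=1e-6
        )
        assert rep1.rmsd_all == pytest.approx(rep2.rmsd_all, abs=1e-9)
        assert rep1.clash_count == rep2.clash_count

    def test_core_surface_disjoint(self, mini_dataset):
        for rec, _ in mini_dataset:
            labels = classify_core_surface(rec)
            assert not np.any((labels == "core") & (labels == "surface"))
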