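"""Euler sampler, exponential schedule, inpainting, confidence selection."""

import numpy as np
import pytest

from chiflow.kinematics import build_atoms
from chiflow.records import ChiSet
from chiflow.sampling import (
    SamplerConfig,
    euler_sample,
    inpaint,
    scheduled_field,
    select_by_confidence,
)
from chiflow.torus import log_map
from chiflow.training import sample_prior_chi

from conftest import apply_rigid, rigid_transform


def oracle_field(target_chi: ChiSet):
    """Exact conditional vector field toward a known endpoint."""

    def field(graph, chi, t):
        denom = max(1.0 - t, 1e-9)
        return log_map(chi.angles, target_chi.angles, chi.periods) / denom * chi.exists

    return field


class TestScheduledField:
    def test_exact_field_recovers_endpoint(self, mini_protein):
        _, chis = mini_protein
        rng = np.random.default_rng(0)
        chi0 = sample_prior_chi(chis, rng)
        for t in (0.0, 0.3, 0.7):
            from chiflow.torus import geodesic_point

            xt = geodesic_point(chi0, chis.angles, t, chis.periods) * chis.exists
            chi_t = ChiSet(xt, chis.exists, chis.symmetric)
            v = log_map(xt, chis.angles, chis.periods) / (1 - t)
            out = scheduled_field(v, chi_t, t, schedule_c=5.0)
            expected = 5.0 * log_map(xt, chis.angles, chis.periods) * chis.exists
            assert np.abs(out - expected)[chis.exists].max() < 1e-9

    def test_zero_at_endpoint_and_bounded(self, mini_protein):
        _, chis = mini_protein
        out = scheduled_field(np.zeros_like(chis.angles), chis, 0.5, schedule_c=5.0)
        assert np.all(out == 0.0)
        rng = np.random.default_rng(1)
        v = rng.normal(scale=10.0, size=chis.angles.shape)
        out = scheduled_field(v, chis, 0.2, schedule_c=5.0)
        assert np.abs(out).max() <= 5.0 * np.pi  # c * period/2 bound


class TestEulerSampler:
    def test_oracle_field_converges_within_one_percent(self, mini_protein):
        """10 steps at c=5 contract the wrapped distance by (1-c*dt)^10."""
        rec, chis = mini_protein
        cfg = SamplerConfig(num_steps=10, schedule_c=5.0, seed=3)
        out = euler_sample(rec, None, cfg, field_fn=oracle_field(chis))
        chi0 = sample_prior_chi(chis, np.random.default_rng(3))
        d0 = np.abs(log_map(chi0, chis.angles, chis.periods))[chis.exists]
        d1 = np.abs(log_map(out.chi.angles, chis.angles, chis.periods))[chis.exists]
        nontrivial = d0 > 1e-3
        assert np.all(d1[nontrivial] / d0[nontrivial] < 0.01)

    def test_single_step_c1_lands_exactly(self, mini_protein):
        rec, chis = mini_protein
        cfg = SamplerConfig(num_steps=1, schedule_c=1.0, seed=4)
        out = euler_sample(rec, None, cfg, field_fn=oracle_field(chis))
        d = np.abs(log_map(out.chi.angles, chis.angles, chis.periods))[chis.exists]
        assert d.max() < 1e-9

    def test_fixed_seed_reproducible(self, mini_protein):
        rec, chis = mini_protein
        cfg = SamplerConfig(seed=5)
        a = euler_sample(rec, None, cfg, field_fn=oracle_field(chis))
        b = euler_sample(rec, None, cfg, field_fn=oracle_field(chis))
        assert np.array_equal(a.chi.angles, b.chi.angles)

    def test_chi_stays_in_canonical_charts(self, mini_protein):
        rec, chis = mini_protein
        out = euler_sample(
            rec, None, SamplerConfig(seed=6, num_steps=4), field_fn=oracle_field(chis)
        )
        ang = out.chi.angles
        sym = out.chi.symmetric & out.chi.exists
        full = ~out.chi.symmetric & out.chi.exists
        assert np.all(ang[sym] >= 0) and np.all(ang[sym] < np.pi)
        assert np.all(ang[full] >= -np.pi) and np.all(ang[full] < np.pi)

    def test_rigid_invariance_of_sampled_chi(self, mini_protein):
        rec, chis = mini_protein
        rng = np.random.default_rng(7)
        R, t = rigid_transform(rng)
        moved = apply_rigid(rec, R, t)
        f = oracle_field(chis)
        a = euler_sample(rec, None, SamplerConfig(seed=8), field_fn=f)
        b = euler_sample(moved, None, SamplerConfig(seed=8), field_fn=f)
        assert np.abs(a.chi.angles - b.chi.angles).max() < 1e-6

    def test_monotone_contraction_under_exponential_schedule(self, mini_protein):
        rec, chis = mini_protein
        cfg = SamplerConfig(num_steps=10, schedule_c=5.0, seed=9)
        dists = []

        def tracking_field(graph, chi, t):
            d = np.abs(log_map(chi.angles, chis.angles, chis.periods))[chis.exists]
            dists.append(d.mean())
            return oracle_field(chis)(graph, chi, t)

        euler_sample(rec, None, cfg, field_fn=tracking_field)
        assert all(b <= a + 1e-12 for a, b in zip(dists, dists[1:]))


class TestInpaint:
    def test_pinned_residues_bit_identical(self, mini_protein):
        rec, chis = mini_protein
        rng = np.random.default_rng(10)
        for frac in (0.05, 0.25, 0.75):
            mask = rng.uniform(size=rec.num_residues) < frac
            out = inpaint(rec, chis, mask, None, SamplerConfig(seed=11, num_steps=3),
                          rng=np.random.default_rng(0), field_fn=oracle_field(chis))
            pinned = ~mask
            assert np.array_equal(out.chi.angles[pinned], chis.angles[pinned])

    def test_empty_mask_returns_known_chi(self, mini_protein):
        rec, chis = mini_protein
        mask = np.zeros(rec.num_residues, bool)
        out = inpaint(rec, chis, mask, None, SamplerConfig(seed=12, num_steps=2),
                      rng=np.random.default_rng(0), field_fn=oracle_field(chis))
        assert np.array_equal(out.chi.angles, chis.angles)

    def test_full_mask_equals_plain_sampling(self, mini_protein):
        rec, chis = mini_protein
        f = oracle_field(chis)
        cfg = SamplerConfig(seed=13, num_steps=4)
        a = euler_sample(rec, None, cfg, rng=np.random.default_rng(13), field_fn=f)
        b = inpaint(rec, chis, np.ones(rec.num_residues, bool), None, cfg,
                    rng=np.random.default_rng(13), field_fn=f)
        assert np.array_equal(a.chi.angles, b.chi.angles)

    def test_mask_shape_validated(self, mini_protein):
        rec, chis = mini_protein
        with pytest.raises(ValueError):
            inpaint(rec, chis, np.ones(3, bool), None, SamplerConfig())


class TestSelectByConfidence:
    def test_single_sample_returned(self, mini_protein):
        rec, chis = mini_protein
        s = euler_sample(rec, None, SamplerConfig(seed=1, num_steps=2),
                         field_fn=oracle_field(chis))
        best, idx, scores = select_by_confidence(rec, [s], score_fn=lambda r, x: np.ones(3))
        assert idx == 0 and best is s

    def test_mocked_scores_argmin_with_tie_break(self, mini_protein):
        rec, chis = mini_protein
        f = oracle_field(chis)
        samples = [
            euler_sample(rec, None, SamplerConfig(seed=k, num_steps=2), field_fn=f)
            for k in range(4)
        ]
        consts = iter([3.0, 1.0, 1.0, 2.0])

        def mock(rec_, s):
            return np.full(rec_.num_residues, next(consts))

        best, idx, scores = select_by_confidence(rec, samples, score_fn=mock)
        assert idx == 1  # first of the tied minima

    def test_true_rmsd_oracle_selects_minimal_rmsd(self, mini_dataset):
        from chiflow.evaluate import per_residue_sidechain_rmsd

        for rec, chis in mini_dataset:
            ref_atoms, ref_mask = build_atoms(rec.backbone, rec.aatype, chis.angles)

            def true_rmsd(rec_, s):
                r, v = per_residue_sidechain_rmsd(
                    s.atom14, ref_atoms, rec_.aatype, s.atom_mask & ref_mask
                )
                return np.where(v, r, 0.0)

            # noisy samples: partial-step oracle fields of varying quality
            samples = [
                euler_sample(
                    rec, None, SamplerConfig(seed=100 + k, num_steps=k + 1, schedule_c=1.0),
                    field_fn=oracle_field(chis),
                )
                for k in range(4)
            ]
            best, idx, scores = select_by_confidence(rec, samples, score_fn=true_rmsd)
            assert idx == int(np.argmin(scores))
            assert scores[idx] == min(scores)

    def test_empty_list_rejected(self, mini_protein):
        rec, _ = mini_protein
        with pytest.raises(ValueError):
            select_by_confidence(rec, [], score_fn=lambda r, s: np.zeros(1))
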