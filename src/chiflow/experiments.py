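"""Reusable desk-scale studies: the configurations and end-to-end runs
exercised by the test suite, the acceptance script, and the examples.

Everything here is deterministic given its seed arguments.  The fixture
specifications are fixed study conditions; the seed controls the
stochastic parts (initialization, noising, sampling).
"""

from __future__ import annotations

import numpy as np

from .evaluate import aggregate_reports, evaluate_structure, per_residue_sidechain_rmsd
from .fixtures import FixtureSpec, make_full_structure
from .kinematics import build_atoms
from .network import NetworkConfig, PackingNetwork
from .records import ChiSet
from .sampling import SamplerConfig, euler_sample, inpaint, select_by_confidence
from .torus import log_map
from .training import TrainConfig, sample_prior_chi, train

__all__ = [
    "STUDY_FIXTURES",
    "desk_train_config",
    "desk_network_config",
    "study_dataset",
    "true_rmsd_oracle",
    "exact_field",
    "train_overfit_model",
    "overfit_recovery_study",
    "inpainting_study",
    "oracle_sampler_convergence",
]

#: the three fixed-seed 40-60 residue fixtures of the overfit study
STUDY_FIXTURES = (
    FixtureSpec(length=40, sequence_seed=1, rotamer_seed=11),
    FixtureSpec(length=50, sequence_seed=2, rotamer_seed=12),
    FixtureSpec(length=60, sequence_seed=3, rotamer_seed=13),
)

#: masking fractions of the inpainting protocol
INPAINT_FRACTIONS = (0.05, 0.10, 0.25, 0.50, 0.75, 1.00)


def desk_network_config(seed=0) -> NetworkConfig:
    """Compact CPU-scale model (~130k parameters)."""
    return NetworkConfig(dim=64, num_layers=2, num_heads=4, init_seed=int(seed))


def desk_train_config(seed=0) -> TrainConfig:
    """CPU-budget training profile (rationale in docs/methods.md)."""
    return TrainConfig(
        learning_rate=2e-3,
        batch_size=1,
        t_epsilon=0.05,
        ema_decay=0.99,
        warmup_iters=100,
        seed=int(seed),
    )


def study_dataset():
    """The fixed fixture set: list of (StructureRecord, ChiSet)."""
    return [make_full_structure(spec) for spec in STUDY_FIXTURES]


def true_rmsd_oracle(record, chi_true: ChiSet):
    """Score function returning the true per-residue side-chain RMSD
    (stands in for the confidence model in oracle-selection studies)."""
    ref_atoms, ref_mask = build_atoms(record.backbone, record.aatype, chi_true.angles)

    def score(rec, sample):
        r, valid = per_residue_sidechain_rmsd(
            sample.atom14, ref_atoms, rec.aatype, sample.atom_mask & ref_mask
        )
        return np.where(valid, r, 0.0)

    return score


def exact_field(chi_true: ChiSet):
    """The exact conditional vector field toward a known endpoint."""

    def field(graph, chi, t):
        denom = max(1.0 - t, 1e-9)
        return log_map(chi.angles, chi_true.angles, chi.periods) / denom * chi.exists

    return field


def train_overfit_model(seed=0, num_iterations=2000, dataset=None):
    """Train the compact model on the study fixtures (EMA weights loaded)."""
    if dataset is None:
        dataset = study_dataset()
    model = PackingNetwork(desk_network_config(seed))
    ema, history = train(dataset, model, desk_train_config(seed), num_iterations)
    model.load_state_dict(ema.state_dict())
    return model, dataset, history


def _evaluate_samples(model, dataset, seed, num_samples=4):
    reports = []
    for idx, (record, chi_true) in enumerate(dataset):
        samples = [
            euler_sample(
                record, model,
                SamplerConfig(seed=0),
                rng=np.random.default_rng([int(seed), 17, idx, k]),
            )
            for k in range(num_samples)
        ]
        best, _, _ = select_by_confidence(
            record, samples, score_fn=true_rmsd_oracle(record, chi_true)
        )
        ref_atoms, ref_mask = build_atoms(record.backbone, record.aatype, chi_true.angles)
        reports.append(
            evaluate_structure(
                record, best.atom14, best.atom_mask, ref_atoms, ref_mask,
                per_residue_table=False,
            )
        )
    return reports


def overfit_recovery_study(seed=0, num_iterations=2000, model=None, dataset=None):
    """Full train -> sample -> select -> evaluate loop on the fixtures.

    Four samples per structure; selection by the true-RMSD oracle.
    Returns the aggregate metric dict plus the trained model.
    """
    if model is None or dataset is None:
        model, dataset, _ = train_overfit_model(seed, num_iterations)
    reports = _evaluate_samples(model, dataset, seed)
    agg = aggregate_reports(reports)
    counts = np.array(
        [sum(r.counts_per_chi[k] for r in reports) for k in range(4)], dtype=float
    )
    acc = np.nan_to_num(np.array(agg["accuracy_per_chi"]))
    agg["accuracy_all_chi"] = float((acc * counts).sum() / counts.sum())
    return agg, model, dataset


def inpainting_study(model, dataset, seed=0, fractions=INPAINT_FRACTIONS):
    """Masked-residue recovery at the protocol's masking grid.

    For each fraction, that share of residues is repacked while the rest
    are pinned to ground truth; MAE is computed on the masked residues
    only.  Returns {fraction: {"chi1_mae_deg": ..., "pinned_exact": ...}}.
    """
    out = {}
    for frac in fractions:
        maes, pinned_ok = [], True
        for idx, (record, chi_true) in enumerate(dataset):
            rng = np.random.default_rng([int(seed), 23, idx, int(frac * 100)])
            R = record.num_residues
            n_mask = max(1, int(round(frac * R)))
            repack = np.zeros(R, dtype=bool)
            repack[rng.choice(R, size=n_mask, replace=False)] = True
            result = inpaint(
                record, chi_true, repack, model,
                SamplerConfig(seed=0),
                rng=np.random.default_rng([int(seed), 29, idx, int(frac * 100)]),
            )
            pinned = ~repack
            pinned_ok &= bool(
                np.array_equal(result.chi.angles[pinned], chi_true.angles[pinned])
            )
            err = np.abs(
                log_map(result.chi.angles, chi_true.angles, chi_true.periods)
            )
            sel = repack[:, None] & chi_true.exists & (np.arange(4) == 0)
            if sel.any():
                maes.append(np.rad2deg(err[sel].mean()))
        out[frac] = {
            "chi1_mae_deg": float(np.mean(maes)),
            "pinned_exact": pinned_ok,
        }
    return out


def oracle_sampler_convergence(seed=0, num_steps=10, schedule_c=5.0):
    """Euler-solver contraction with the exact conditional field.

    Returns the worst final/initial wrapped-distance ratio over the study
    fixtures (theory: |1 - c/num_steps|^num_steps).
    """
    worst = 0.0
    for idx, spec in enumerate(STUDY_FIXTURES):
        record, chi_true = make_full_structure(spec)
        rng_seed = [int(seed), 31, idx]
        out = euler_sample(
            record, None,
            SamplerConfig(num_steps=num_steps, schedule_c=schedule_c, seed=0),
            rng=np.random.default_rng(rng_seed),
            field_fn=exact_field(chi_true),
        )
        chi0 = sample_prior_chi(chi_true, np.random.default_rng(rng_seed))
        d0 = np.abs(log_map(chi0, chi_true.angles, chi_true.periods))[chi_true.exists]
        d1 = np.abs(log_map(out.chi.angles, chi_true.angles, chi_true.periods))[
            chi_true.exists
        ]
        keep = d0 > 1e-3
        worst = max(worst, float((d1[keep] / d0[keep]).max()))
    return worst
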