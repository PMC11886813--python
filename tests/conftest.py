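import numpy as np
import pytest

from chiflow.fixtures import FixtureSpec, make_full_structure
from chiflow.kinematics import build_atoms


@pytest.fixture(scope="session")
def mini_protein():
    """One 40-residue mixed-SS fixture with ground-truth chi."""
    return make_full_structure(FixtureSpec(length=40, sequence_seed=1, rotamer_seed=11))


@pytest.fixture(scope="session")
def mini_dataset():
    """Three fixed-seed 40-60 residue fixtures (the overfit study set)."""
    return [
        make_full_structure(FixtureSpec(length=n, sequence_seed=s, rotamer_seed=s + 10))
        for n, s in ((40, 1), (50, 2), (60, 3))
    ]


@pytest.fixture(scope="session")
def dimer():
    """Two-chain fixture for multimer edge handling."""
    return make_full_structure(
        FixtureSpec(length=24, chains=2, sequence_seed=5, rotamer_seed=6)
    )


def rigid_transform(rng):
    """A random rotation + translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.normal(scale=20.0, size=3)
    return R, t


def apply_rigid(record, R, t):
    rec = record.copy()
    rec.backbone = record.backbone @ R.T + t
    rec.atom14 = record.atom14 @ R.T + t
    rec.atom14[~record.atom_mask] = 0.0
    return rec


def reference_atoms(record, chiset):
    return build_atoms(record.backbone, record.aatype, chiset.angles)
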