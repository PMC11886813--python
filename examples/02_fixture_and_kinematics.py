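"""Build a synthetic mini-protein and round-trip its chi angles.

Shows the fixture generator (ideal backbone + known rotamers), full-atom
reconstruction from chi angles, and chi measurement from coordinates.
"""

import numpy as np

from chiflow.fixtures import FixtureSpec, make_full_structure
from chiflow.kinematics import build_atoms, measure_chi_all, reduce_symmetry
from chiflow.torus import log_map

spec = FixtureSpec(length=40, sequence_seed=1, rotamer_seed=11, secondary_structure="mixed")
record, chi_true = make_full_structure(spec)

print("sequence:", record.sequence)
print("residues:", record.num_residues, "| chi angles:", int(chi_true.exists.sum()))

# measuring chi from the built coordinates recovers the generating rotamers
measured = reduce_symmetry(measure_chi_all(record))
err = np.abs(log_map(measured.angles, chi_true.angles, chi_true.periods))
print("max chi measurement error (rad):", err[chi_true.exists].max())

# rebuilding atoms from the measured angles reproduces the structure
atoms, mask = build_atoms(record.backbone, record.aatype, measured.angles)
d = np.linalg.norm(atoms - record.atom14, axis=-1)[record.atom_mask]
print("max atom deviation after rebuild (A):", d.max())
# both numbers are at float precision: chi angles are a lossless
# parameterization of idealized side-chain geometry
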