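"""Geodesics and conditional vector fields on the chi torus.

Builds the conditional flow between a prior angle and a data angle and
checks the identities the training loss and sampler rely on.
"""

import numpy as np

from chiflow.torus import (
    conditional_vector_field,
    exp_map,
    geodesic_point,
    log_map,
    sample_uniform_prior,
)

chi0 = sample_uniform_prior(5, seed=1)          # prior draws, chart [-pi, pi)
chi1 = sample_uniform_prior(5, seed=2)          # "data" angles

print("chi0 (deg):", np.round(np.rad2deg(chi0), 1))
print("chi1 (deg):", np.round(np.rad2deg(chi1), 1))

arc = log_map(chi0, chi1)
print("shortest arc chi0 -> chi1 (deg):", np.round(np.rad2deg(arc), 1))
# the arc never exceeds half a turn: the flow takes the short way round
assert np.all(np.abs(arc) <= np.pi)

mid = geodesic_point(chi0, chi1, 0.5)
print("geodesic midpoint (deg):", np.round(np.rad2deg(mid), 1))

# the conditional vector field of the linear schedule is constant in t and
# equals the full arc: integrating it for unit time lands exactly on chi1
v = conditional_vector_field(chi0, chi1)
landed = exp_map(chi0, v)
print("exp_map(chi0, v) - chi1 (wrapped):", np.round(log_map(landed, chi1), 12))
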