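# Methods

`chiflow` predicts protein side-chain conformations — the chi dihedral
angles of every residue — conditioned on the sequence and a fixed backbone,
by flow matching on the product torus of those angles.  This note records
the model, its assumptions, the numerical choices, and what the synthetic
test bed does and does not establish.

## State space and geometry

Under idealized bond lengths and angles, a residue's side chain is fully
determined by up to four dihedrals chi1..chi4, so a protein's side-chain
conformation is a point on a product of circles (a hypertorus).  Some chi
angles are pi-periodic rather than 2*pi-periodic because a 180-degree
rotation of their terminal group produces a chemically identical atom set;
by default these are chi2 of ASP/PHE/TYR and chi3 of GLU (the usual
crystallographic convention; the flag set is configuration, and amide/
imidazole/guanidinium flips are deliberately *not* reduced by default).
Each angle carries its own period, with canonical charts [-pi, pi) for the
full circle and [0, pi) for symmetry-reduced angles.

All geometry is closed form (`chiflow.torus`): the exponential map is
wrapped addition, the logarithmic map the signed shortest arc (computed
with exact modular arithmetic so exp/log invert to machine precision; the
antipodal tie resolves deterministically to +period/2), and the conditional
flow of the linear schedule interpolates along geodesics,

    chi_t = exp_{chi0}( t * log_{chi0}(chi1) ),    t in [0, 1],

with the conditional vector field constant along the path and equal to
`log_{chi0}(chi1)`.  The endpoint parameterization
`log_{chi_t}(chi1) / (1 - t)` is also provided; the two coincide along
exact geodesics.  The `/(1-t)` form guards `t >= 1 - 1e-5` by returning the
undivided arc, avoiding the division blow-up at the data endpoint.

## Kinematics

Residue templates (`chiflow/data/residue_topology.json`, schema documented
in the file) define the atom14 layout, the chi-defining atom quadruples,
and one internal-coordinate build record per side-chain heavy atom
(bond length, bond angle, and a dihedral that is either a chi angle, a chi
angle plus a branch offset, or a ring constant).  Bond lengths and angles
are Engh–Huber-style ideal values.  Full-atom reconstruction is sequential
NeRF placement; chi measurement is the standard signed dihedral (IUPAC,
cis = 0).  The two are exact inverses on the chi-defining atoms, which the
test suite verifies for all 18 chi-bearing residue types.

Numerical/structural choices:

* C-beta is placed by a fixed tetrahedral construction (bond 1.526 A,
  angle N-CA-CB 110.4 deg, improper C-N-CA-CB -122.5 deg); glycine gets a
  virtual C-beta by the same rule wherever a node position or burial count
  needs one.
* PHE/TYR ring angles are set to exactly 120 degrees so the ring is a
  regular planar hexagon: this makes the pi-flip map the heavy-atom set
  onto itself exactly (an irregular ring breaks flip symmetry at the
  ~0.05 A level), which the symmetry-reduction of chi2 presumes.
* TRP/HIS/PRO rings are built along one branch with a closure bond that is
  only approximately ideal; they carry no pi-symmetric chi, so nothing
  depends on their exact closure.  Proline's chi2 is treated as a free
  torsion (ring closure not enforced) — a known limitation.
* OXT and hydrogens are excluded everywhere; unknown residues carry a
  21st identity class and an empty chi mask.

## Featurization

Residues are graph nodes at their idealized C-beta, connected to their
k = 30 nearest neighbors (Euclidean C-beta distance, directed edges,
deterministic tie-break toward the lower residue index; squared distances
are quantized at 1e-6 before the tie-break so the exact ties of idealized
geometry survive the rounding noise of a rigid transform).  Node features:
21-way identity one-hot, sin/cos of phi/psi/omega with validity bits
(chain-terminal torsions zeroed), and a 32-dim sinusoidal embedding of the
flow time.  Edge features: a 65-bin one-hot of the clamped sequence offset
(cross-chain edges pinned to the +32 bin — the multimer rule) and the
14 x 14 pairwise distances between the two residues' *current* (noised or
partially integrated) atom14 coordinates, with validity bits for missing
atoms.  Atoms are rebuilt from the current chi state before every network
call, so edge distances always reflect the state being denoised.  All
features are rigid-motion invariant.  An optional Gaussian radial-basis
expansion of the distances (width/centers configurable) is available; the
default feeds raw distances through a normalized embedding, which proved
equally accurate and considerably cheaper at small scale.

## Network

The denoiser is a pre-LN multi-head graph-attention network over the k-NN
graph: edge-conditioned messages m_ij = GELU(W [h_i; h_j; e_ij]), per-node
softmax attention with m as key and value, residual feed-forward blocks.
Because every input is an invariant scalar, the predicted quantities
(tangent vector fields per chi, per-residue RMSD) are exactly invariant
under rigid motions and exactly equivariant under residue relabeling; an
equivariant architecture is unnecessary for torsional targets.  The current
chi state enters as masked sin/cos channels appended to the node features.

The output head is an inner product between trunk-derived coefficients and
a Fourier basis of the current angle (order 8 by default, in each angle's
own period):

    v_hat_k = < W_k h , [1, sin theta_k, cos theta_k, ..., sin M theta_k, cos M theta_k] >.

The conditional field, viewed as a function of the current angle with the
endpoint fixed, is a sawtooth; its Fourier coefficients are smooth
functions of the endpoint, so the trunk only has to regress per-residue
coefficients (near-constant targets, which small models memorize quickly)
instead of approximating a wrapped difference end to end.  Truncation
error (Gibbs) concentrates at the antipode of the endpoint — a region the
contracting sampler leaves within the first steps.  The output remains an
unbounded tangent value.  A plain linear head is recoverable with
`fourier_order=0` plus the sin/cos node channels, but converged an order of
magnitude slower in our small-scale probes.

Defaults are a compact model (2 blocks, 64 channels, 4 heads, ~130k
parameters) sized for CPU experiments; 4 blocks at 256 channels reproduces
the reference scale of this architecture family.  The confidence model is
the same trunk at reduced width with a softplus scalar head regressing
per-residue side-chain RMSD.

## Training

Conditional flow matching: per structure, draw chi0 uniform on each
angle's chart, t ~ U(0, 1 - t_eps), interpolate chi_t along the geodesic,
and regress the predicted field on the constant conditional field with the
weighted loss

    L = (1 / (1 - t)^2) * mean_masked || v_hat - log_{chi0}(chi1) ||^2 .

Pi-symmetric angles live in their reduced chart throughout, so their
targets never exceed pi/2.  Optimization is AdamW (lr 1e-4 default,
gradient-norm clip 1.0), contiguous per-chain crops to 512 residues, and
an exponential moving average of the weights (decay 0.999 default) used
for sampling.

`t_eps` defaults to 1e-3.  The desk-scale profile used by the tests and
the acceptance script sets `t_eps = 0.05`, a higher learning rate (2e-3),
warmup, and a shorter EMA window (decay 0.99): with t allowed up to
1 - 1e-3 the weight spans six orders of magnitude and concentrates ~99% of
the expected gradient at t > 0.9 — times the 10-step Euler grid never
queries — which at a 2000-iteration budget is spent variance.  These are
training-profile choices, not changes to the loss.

Confidence training samples one conformation per structure visit with the
EMA weights, computes the true per-residue heavy-atom RMSD (no
superposition; symmetric terminal pairs matched), and regresses the
confidence head with squared error.

## Sampling

chi(0) is drawn from the uniform torus prior and integrated for 10 uniform
Euler steps.  The network output v_hat (trained against the constant field
of the linear schedule) is converted to an endpoint estimate
`chi1_hat = exp_{chi_t}((1 - t) v_hat)` — the exact inversion of the
training parameterization along geodesics — and the integrated field is
the exponential schedule `c * log_{chi_t}(chi1_hat)` with c = 5.  With the
exact field substituted for the network, each step contracts the wrapped
distance to the target by |1 - c dt| = 0.5, i.e. about 1e-3 over ten steps;
a single step at c = 1 lands exactly.  The final state is reported at t = 1
without an extra field evaluation.  Atoms are rebuilt and the graph
refeaturized at every step.

Inpainting pins known residues' chi to their reference values at every
step (outputs are bit-identical at pinned residues) while they contribute
context through the rebuilt atoms.  Multimers need no special casing
beyond the +32 cross-chain relative-position bin.  Among multiple samples,
the one with the lowest mean predicted per-residue RMSD is selected (ties
break toward the lower sample index).

## Evaluation

Angle MAE is the minimum arc on each angle's circle, in degrees (<= 180,
or <= 90 for pi-symmetric angles); accuracy is the fraction of angles
strictly within 20 degrees; both are micro-averaged over all residues of
all structures (macro averaging is an option).  Per-residue RMSD covers
side-chain heavy atoms beyond C-beta, without superposition, with
ASP/GLU/PHE/TYR symmetric terminal pairs matched to minimize the value;
ALA/GLY are excluded.  Core residues have >= 20 other C-betas within 10 A,
surface residues <= 15; the classes are disjoint, with an unlabeled band
between.  Clashes are non-bonded heavy-atom pairs closer than the sum of
van der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80 A) minus 0.4 A,
excluding same-residue pairs and pairs within three bonds across the
peptide link (the 1-4 exclusion is required: the ubiquitous trans-peptide
O_i...CA_{i+1} contact sits at 2.78 A, inside the 1-3-only threshold).
The overlap tolerance and exclusion depth are configuration.

## Synthetic data

The fixture generator (`chiflow.fixtures`) grows ideal-geometry backbones
at canonical (phi, psi) — helix (-57, -47), strand (-139, 135), or mixed
segments of 8-12 residues — with trans peptides, places chains of a
multimer with a 16 A bounding-box gap (beyond twice the maximal side-chain
reach, so chains cannot clash), and draws chi angles from the classical
gauche+/gauche-/trans rotamer centers with 5-degree Gaussian jitter
(enough variance that recovery tests cannot succeed by predicting rotamer
bins alone, small enough to be learnable).  Sequences are random with every
chi-bearing residue type guaranteed present in a default-sized fixture.
Ground-truth ChiSets are exact by construction.

What fixtures do not emulate: real rotamer statistics and their backbone
dependence, packing energetics (random rotamers interpenetrate — clash
counts on dense fixtures are large by design), crystallographic noise,
missing atoms, or alternate conformations.  Tests passing on fixtures
therefore establish the *machinery* — geometry, kinematics, featurization,
optimization, solver, metrics — not biophysical accuracy on real proteins,
which requires training at full scale on curated structure sets.

## Problem sizes

The test suite and acceptance script run on three fixed-seed fixtures of
40-60 residues (single chain, mixed secondary structure) and a two-chain
24+24-residue complex; the overfit study trains the compact model for
2000 iterations (a few minutes on one CPU) and evaluates recovery on the
training fixtures with four samples and RMSD-based selection.  These sizes
were chosen so the full train-sample-evaluate loop is exercised end to end
at interactive timescales.

## Known limitations

* Proline ring closure is not enforced; its chi1/chi2 are treated as free.
* Idealized reconstruction cannot reproduce the small bond-length/angle
  deviations of real structures; atom-level accuracy is bounded by the
  idealization (~0.1 A against experimental coordinates).
* The clash criterion is a fixed-radius overlap rule, not an energy.
* The confidence model shares the training fixtures with the main model in
  the desk-scale protocol; its ranking is validated against a true-RMSD
  oracle rather than held-out data.
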