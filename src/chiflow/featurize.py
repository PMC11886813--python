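"""Residue-level graph construction and feature tensors for the network.

Residues are nodes positioned at their idealized C-beta atom (virtual for
glycine); edges connect each residue to its k nearest neighbors (k = 30 by
default).  Node features are the one-hot amino-acid identity, sin/cos of
the backbone torsions phi/psi/omega with validity bits, and a sinusoidal
embedding of the flow time t.  Edge features are a one-hot relative
positional encoding clamped at [-32, 32] (cross-chain edges pinned to the
+32 bin) plus the 14 x 14 pairwise distances between the two residues'
current (noised) atom14 coordinates with per-pair validity bits.

Every feature is invariant under rigid motions of the input coordinates,
which is what makes an invariant network sufficient for torsional targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import _dihedral_masked, idealize_cbeta
from .records import StructureRecord
from .residues import ATOM14, NUM_AA_CLASSES

__all__ = [
    "PackingGraph",
    "knn_edges",
    "backbone_torsions",
    "node_features",
    "edge_features",
    "multimer_relpos",
    "build_graph",
    "NODE_DIM",
    "EDGE_DIM",
]

DEFAULT_K = 30
RELPOS_CLAMP = 32
RELPOS_BINS = 2 * RELPOS_CLAMP + 1  # 65
TIME_EMBED_DIM = 32

NODE_DIM = NUM_AA_CLASSES + 6 + 3 + TIME_EMBED_DIM  # 62
EDGE_DIM = RELPOS_BINS + ATOM14 * ATOM14 + ATOM14 * ATOM14  # 65 + 196 + 196 = 457


@dataclass
class PackingGraph:
    """k-NN residue graph with dense feature tensors."""

    node_features: np.ndarray  # (R, NODE_DIM)
    edge_index: np.ndarray     # (E, 2) int, (target, source) pairs
    edge_features: np.ndarray  # (E, EDGE_DIM)
    knn_k: int

    @property
    def num_nodes(self):
        return self.node_features.shape[0]


def knn_edges(cbeta_coords, k=DEFAULT_K):
    """Directed k-NN edges by Euclidean C-beta distance.

    Each residue receives edges from its ``min(k, R-1)`` nearest other
    residues; distance ties break deterministically toward the lower
    residue index.  Returns an (E, 2) array of (target, source) pairs
    sorted by target then by proximity rank.
    """
    x = np.asarray(cbeta_coords, dtype=float)
    R = x.shape[0]
    if R < 2:
        raise ValueError("need at least 2 residues for a k-NN graph")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    k_eff = min(int(k), R - 1)
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    # quantize so exact ties (frequent in idealized geometry) break by index
    # even after the ~1e-13 rounding noise of a rigid transform
    d2 = np.round(d2, 6)
    np.fill_diagonal(d2, np.inf)
    idx = np.arange(R)
    order = np.lexsort((np.broadcast_to(idx, (R, R)), d2), axis=1)  # dist, then index
    nbr = order[:, :k_eff]
    tgt = np.repeat(idx, k_eff)
    return np.stack([tgt, nbr.reshape(-1)], axis=1)


def backbone_torsions(structure: StructureRecord):
    """(R, 3) phi/psi/omega radians and (R, 3) validity (chain-aware).

    phi_i = C_{i-1}-N_i-CA_i-C_i, psi_i = N_i-CA_i-C_i-N_{i+1},
    omega_i = CA_{i-1}-C_{i-1}-N_i-CA_i; torsions spanning a chain
    boundary (or either terminus) are invalid.
    """
    bb = structure.backbone
    R = bb.shape[0]
    chains = structure.chain_ids
    same_prev = np.zeros(R, dtype=bool)
    same_prev[1:] = chains[1:] == chains[:-1]
    same_next = np.zeros(R, dtype=bool)
    same_next[:-1] = chains[:-1] == chains[1:]

    tor = np.zeros((R, 3))
    valid = np.zeros((R, 3), dtype=bool)
    if R > 1:
        phi, ok = _dihedral_masked(bb[:-1, 2], bb[1:, 0], bb[1:, 1], bb[1:, 2])
        tor[1:, 0] = phi
        valid[1:, 0] = ok & same_prev[1:]
        psi, ok = _dihedral_masked(bb[:-1, 0], bb[:-1, 1], bb[:-1, 2], bb[1:, 0])
        tor[:-1, 1] = psi
        valid[:-1, 1] = ok & same_next[:-1]
        omg, ok = _dihedral_masked(bb[:-1, 1], bb[:-1, 2], bb[1:, 0], bb[1:, 1])
        tor[1:, 2] = omg
        valid[1:, 2] = ok & same_prev[1:]
    return tor * valid, valid


def time_embedding(t, dim=TIME_EMBED_DIM):
    """Sinusoidal embedding of t in [0, 1]: geometric frequency ladder."""
    half = dim // 2
    freqs = 2.0 * np.pi * np.geomspace(1.0, 1000.0, half)
    phases = float(t) * freqs
    return np.concatenate([np.sin(phases), np.cos(phases)])


def node_features(structure: StructureRecord, t):
    """(R, NODE_DIM) rigid-motion-invariant node features at flow time t."""
    R = structure.num_residues
    onehot = np.zeros((R, NUM_AA_CLASSES))
    onehot[np.arange(R), np.minimum(structure.aatype, NUM_AA_CLASSES - 1)] = 1.0

    tor, valid = backbone_torsions(structure)
    sc = np.zeros((R, 6))
    sc[:, 0::2] = np.sin(tor) * valid
    sc[:, 1::2] = np.cos(tor) * valid

    temb = np.broadcast_to(time_embedding(t), (R, TIME_EMBED_DIM))
    return np.concatenate([onehot, sc, valid.astype(float), temb], axis=1)


def multimer_relpos(chain_ids, i, j):
    """Relative-position bin of edge (i <- j): clamp(j - i) within a chain,
    the constant +32 bin across chains (the multimer rule)."""
    chain_ids = np.asarray(chain_ids)
    i = np.asarray(i)
    j = np.asarray(j)
    same = chain_ids[i] == chain_ids[j]
    off = np.clip(j - i, -RELPOS_CLAMP, RELPOS_CLAMP)
    return np.where(same, off + RELPOS_CLAMP, 2 * RELPOS_CLAMP)


def edge_features(structure: StructureRecord, atoms_t, edge_index):
    """(E, EDGE_DIM) edge features from the current (noised) atom14 coords.

    Layout: [relpos one-hot (65) | 196 pairwise atom distances | 196 pair
    validity bits].  Distances involving missing atoms are zero with the
    validity bit off.
    """
    atoms_t = np.asarray(atoms_t, dtype=float)
    ei = np.asarray(edge_index)
    tgt, src = ei[:, 0], ei[:, 1]

    bins = multimer_relpos(structure.chain_ids, tgt, src)
    rel = np.zeros((len(ei), RELPOS_BINS))
    rel[np.arange(len(ei)), bins] = 1.0

    a = atoms_t[tgt]  # (E, 14, 3)
    b = atoms_t[src]
    d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)  # (E, 14, 14)
    pair_ok = (
        structure.atom_mask[tgt][:, :, None] & structure.atom_mask[src][:, None, :]
    )
    d = d * pair_ok
    return np.concatenate(
        [rel, d.reshape(len(ei), -1), pair_ok.reshape(len(ei), -1).astype(float)], axis=1
    )


def cbeta_coords(structure: StructureRecord):
    """Idealized C-beta per residue (virtual for GLY), the node positions."""
    bb = structure.backbone
    return idealize_cbeta(bb[:, 0], bb[:, 1], bb[:, 2])


def build_graph(structure: StructureRecord, atoms_t, t, k=DEFAULT_K) -> PackingGraph:
    """Assemble the full PackingGraph for one structure at flow time t."""
    ei = knn_edges(cbeta_coords(structure), k=k)
    return PackingGraph(
        node_features=node_features(structure, t),
        edge_index=ei,
        edge_features=edge_features(structure, atoms_t, ei),
        knn_k=min(int(k), structure.num_residues - 1),
    )
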