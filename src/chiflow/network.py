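"""Graph-attention vector-field predictor and confidence head.

The denoiser is a compact multi-head graph-attention network over the k-NN
residue graph: edge-conditioned messages, per-node softmax attention,
residual feed-forward blocks.  All of its inputs are rigid-motion-invariant
scalars (torsions, distances, sequence encodings), so its outputs — tangent
vector fields on the chi torus and per-residue RMSD estimates — inherit
invariance by construction; side-chain packing does not require an
equivariant architecture for these targets.

The current chi state enters as masked sin/cos channels appended to the
node features; the flow time t is already embedded in the node features by
:mod:`chiflow.featurize`.  The default configuration is a deliberately
small model for CPU-scale experiments; `dim=256, num_layers=4` reproduces
the reference scale of the architecture family.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .featurize import EDGE_DIM, NODE_DIM, PackingGraph, RELPOS_BINS
from .nn import MLP, LayerNorm, Linear, Module, Tensor, concat, gather, segment_softmax, segment_sum
from .records import ChiSet
from .residues import ATOM14, MAX_CHI

__all__ = [
    "NetworkConfig",
    "PackingNetwork",
    "ConfidenceNetwork",
    "save_checkpoint",
    "load_checkpoint",
]

CHI_FEATURE_DIM = 3 * MAX_CHI  # sin, cos, exists per chi
_N_DIST = ATOM14 * ATOM14

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    rbf_centers = 0 feeds raw pairwise distances to the edge embedding;
    a positive value expands each distance in that many Gaussian radial
    basis functions spaced over [0, rbf_max] Angstrom first.
    """

    dim: int = 64
    num_layers: int = 2
    num_heads: int = 4
    ffn_mult: int = 2
    rbf_centers: int = 0
    rbf_max: float = 20.0
    fourier_order: int = 8
    init_seed: int = 0

    @property
    def edge_input_dim(self):
        if self.rbf_centers <= 0:
            return EDGE_DIM
        return RELPOS_BINS + _N_DIST * self.rbf_centers + _N_DIST

    @property
    def node_input_dim(self):
        return NODE_DIM + CHI_FEATURE_DIM


def _chi_features(chiset: ChiSet):
    ang = chiset.angles
    ex = chiset.exists
    return np.concatenate([np.sin(ang) * ex, np.cos(ang) * ex, ex.astype(float)], axis=1)


def _expand_edges(edge_features, config: NetworkConfig):
    """Optional Gaussian RBF expansion of the distance block."""
    if config.rbf_centers <= 0:
        return edge_features
    rel = edge_features[:, :RELPOS_BINS]
    dist = edge_features[:, RELPOS_BINS : RELPOS_BINS + _N_DIST]
    valid = edge_features[:, RELPOS_BINS + _N_DIST :]
    centers = np.linspace(0.0, config.rbf_max, config.rbf_centers)
    width = centers[1] - centers[0]
    rbf = np.exp(-((dist[:, :, None] - centers) ** 2) / (2 * width**2))
    rbf *= valid[:, :, None]
    return np.concatenate([rel, rbf.reshape(len(dist), -1), valid], axis=1)


class _AttentionBlock(Module):
    def __init__(self, dim, heads, ffn_mult, rng):
        if dim % heads:
            raise ValueError("dim must be divisible by num_heads")
        self.heads = heads
        self.dh = dim // heads
        self.ln_attn = LayerNorm(dim)
        self.ln_ffn = LayerNorm(dim)
        self.w_query = Linear(dim, dim, rng)
        self.w_message = Linear(3 * dim, dim, rng)
        self.w_value = Linear(dim, dim, rng)
        self.w_out = Linear(dim, dim, rng)
        self.ffn = MLP(dim, ffn_mult * dim, dim, rng)

    def __call__(self, h, e, tgt, src, num_nodes):
        E = len(tgt)
        hn = self.ln_attn(h)
        q = gather(self.w_query(hn), tgt)                      # (E, dim)
        m = self.w_message(concat([gather(hn, tgt), gather(hn, src), e])).gelu()
        logits = (q.reshape(E, self.heads, self.dh) * m.reshape(E, self.heads, self.dh)).sum(
            axis=-1
        ) / np.sqrt(self.dh)                                   # (E, heads)
        alpha = segment_softmax(logits, tgt, num_nodes)
        v = self.w_value(m).reshape(E, self.heads, self.dh)
        weighted = (v * alpha.reshape(E, self.heads, 1)).reshape(E, self.heads * self.dh)
        agg = segment_sum(weighted, tgt, num_nodes)            # (R, dim)
        h = h + self.w_out(agg)
        return h + self.ffn(self.ln_ffn(h))


class _GraphTrunk(Module):
    def __init__(self, config: NetworkConfig):
        rng = np.random.default_rng(config.init_seed)
        self.config = config
        self.node_embed = Linear(config.node_input_dim, config.dim, rng)
        self.edge_embed = Linear(config.edge_input_dim, config.dim, rng)
        # raw distance features are far from unit scale; normalize the embedding
        self.ln_edge = LayerNorm(config.dim)
        self.blocks = [
            _AttentionBlock(config.dim, config.num_heads, config.ffn_mult, rng)
            for _ in range(config.num_layers)
        ]
        self.ln_out = LayerNorm(config.dim)

    def __call__(self, graph: PackingGraph, chiset: ChiSet):
        x = np.concatenate([graph.node_features, _chi_features(chiset)], axis=1)
        if x.shape[1] != self.config.node_input_dim:
            raise ValueError("node feature dimension mismatch")
        e_in = _expand_edges(graph.edge_features, self.config)
        tgt, src = graph.edge_index[:, 0], graph.edge_index[:, 1]
        h = self.node_embed(Tensor(x))
        e = self.ln_edge(self.edge_embed(Tensor(e_in)))
        for block in self.blocks:
            h = block(h, e, tgt, src, graph.num_nodes)
        return self.ln_out(h)


def _harmonics(chiset: ChiSet, order):
    """(R, 4, 2*order+1) Fourier basis of each angle in its own period:
    [1, sin(k*theta), cos(k*theta), ...] with theta rescaled to 2*pi."""
    scale = 2.0 * np.pi / chiset.periods
    theta = scale * chiset.angles
    feats = [np.ones_like(theta)]
    for m in range(1, order + 1):
        feats.append(np.sin(m * theta))
        feats.append(np.cos(m * theta))
    return np.stack(feats, axis=-1)


class PackingNetwork(Module):
    """Predicts the tangent vector field, up to 4 values per residue.

    The output head is an inner product between trunk-derived Fourier
    coefficients and harmonics of the current angle:
    ``v_hat_k = <W_k h, phi(chi_k)>``.  The conditional field of a geodesic
    is a circular (sawtooth-like) function of the current angle, so making
    the harmonic basis explicit lets the trunk regress smooth per-residue
    coefficients instead of approximating the wrapped difference itself —
    which converges far faster at small scale.  The output remains an
    unbounded tangent value (no squashing).
    """

    def __init__(self, config: NetworkConfig = NetworkConfig()):
        self.config = config
        self.trunk = _GraphTrunk(config)
        rng = np.random.default_rng(config.init_seed + 1)
        self.n_basis = 2 * config.fourier_order + 1
        self.head = Linear(config.dim, MAX_CHI * self.n_basis, rng)

    def __call__(self, graph: PackingGraph, chiset: ChiSet) -> Tensor:
        """Differentiable forward pass: (R, 4) tangent values (unmasked)."""
        h = self.trunk(graph, chiset)
        coeffs = self.head(h).reshape(graph.num_nodes, MAX_CHI, self.n_basis)
        basis = Tensor(_harmonics(chiset, self.config.fourier_order))
        return (coeffs * basis).sum(axis=-1)

    def predict_vector_field(self, graph: PackingGraph, chiset: ChiSet):
        """(R, 4) numpy field with non-existent chi entries zeroed."""
        out = self(graph, chiset).data
        return out * chiset.exists


class ConfidenceNetwork(Module):
    """Regresses per-residue side-chain heavy-atom RMSD of a finished sample.

    Softplus output guarantees nonnegativity.
    """

    def __init__(self, config: NetworkConfig = NetworkConfig(dim=32, num_layers=1)):
        self.config = config
        self.trunk = _GraphTrunk(config)
        rng = np.random.default_rng(config.init_seed + 2)
        self.head = Linear(config.dim, 1, rng)

    def __call__(self, graph: PackingGraph, chiset: ChiSet) -> Tensor:
        return self.head(self.trunk(graph, chiset)).softplus().reshape(-1)

    def predict_rmsd(self, graph: PackingGraph, chiset: ChiSet):
        return self(graph, chiset).data


def save_checkpoint(path, model: Module, extra=None):
    """Serialize parameters + config to .npz (versioned format)."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "model_class": type(model).__name__,
        "config": asdict(model.config),
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path):
    """Rebuild a network from :func:`save_checkpoint` output."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
        config = NetworkConfig(**meta["config"])
        cls = {"PackingNetwork": PackingNetwork, "ConfidenceNetwork": ConfidenceNetwork}[
            meta["model_class"]
        ]
        model = cls(config)
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model
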