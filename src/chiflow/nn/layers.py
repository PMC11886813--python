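"""Parameterized building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, gather, layer_norm, segment_sum

__all__ = ["Module", "Linear", "MLP", "LayerNorm", "segment_softmax"]


class Module:
    """Base class: recursive parameter registry keyed by dotted names."""

    def parameters(self):
        out = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for sub, p in val.parameters().items():
                    out[f"{name}.{sub}"] = p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = p
        return out

    def num_parameters(self):
        return int(sum(p.data.size for p in self.parameters().values()))

    def zero_grad(self):
        for p in self.parameters().values():
            p.grad = None

    def state_dict(self):
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def load_state_dict(self, state):
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, d_in, d_out, rng, bias=True):
        scale = np.sqrt(2.0 / (d_in + d_out))  # Glorot
        self.weight = Tensor(rng.normal(0.0, scale, size=(d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x):
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class MLP(Module):
    """Two-layer GELU MLP."""

    def __init__(self, d_in, d_hidden, d_out, rng):
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)

    def __call__(self, x):
        return self.fc2(self.fc1(x).gelu())


class LayerNorm(Module):
    def __init__(self, dim):
        self.weight = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x):
        return layer_norm(x, self.weight, self.bias)


def segment_softmax(logits, segment_ids, num_segments):
    """Softmax over rows sharing a segment id (per-node attention weights).

    The per-segment max is subtracted as a constant for numerical
    stability; softmax is invariant to it so gradients are unaffected.
    """
    seg_max = np.full((num_segments,) + logits.data.shape[1:], -np.inf)
    np.maximum.at(seg_max, segment_ids, logits.data)
    shifted = logits - Tensor(seg_max[segment_ids])
    ex = shifted.exp()
    denom = gather(segment_sum(ex, segment_ids, num_segments), segment_ids)
    return ex / denom
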