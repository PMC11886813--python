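"""AdamW optimizer, global gradient-norm clipping, and parameter EMA."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW", "clip_grad_norm", "EMA"]


def clip_grad_norm(params, max_norm):
    """Scale gradients so their global L2 norm is at most ``max_norm``.

    Returns the pre-clip norm (useful for logging).
    """
    grads = [p.grad for p in params.values() if p.grad is not None]
    total = float(np.sqrt(sum(float((g**2).sum()) for g in grads)))
    if max_norm is not None and total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for g in grads:
            g *= scale
    return total


class AdamW(object):
    """Decoupled weight-decay Adam (Loshchilov & Hutter defaults)."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


class EMA:
    """Exponential moving average of parameters, updated every iteration.

    shadow <- decay * shadow + (1 - decay) * current
    """

    def __init__(self, params, decay=0.999):
        if not 0.0 < decay < 1.0:
            raise ValueError("EMA decay must be in (0, 1)")
        self.decay = decay
        self.shadow = {k: p.data.copy() for k, p in params.items()}

    def update(self, params):
        d = self.decay
        for k, p in params.items():
            self.shadow[k] = d * self.shadow[k] + (1.0 - d) * p.data

    def state_dict(self):
        return {k: v.copy() for k, v in self.shadow.items()}
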