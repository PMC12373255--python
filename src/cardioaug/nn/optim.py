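"""Adam / AdamW optimisers for the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "AdamW"]


class Adam:
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2 = lr, betas[0], betas[1]
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def _decay(self, p: Tensor):
        # plain Adam: L2 folded into the gradient
        if self.weight_decay:
            return p.grad.data + self.weight_decay * p.data
        return p.grad.data

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = self._decay(p)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
            self._post(p)

    def _post(self, p):
        pass


class AdamW(Adam):
    """Adam with decoupled weight decay."""

    def _decay(self, p: Tensor):
        return p.grad.data

    def _post(self, p: Tensor):
        if self.weight_decay:
            p.data -= self.lr * self.weight_decay * p.data
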