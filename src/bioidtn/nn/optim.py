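"""First-order optimizers: SGD, RMSProp and Adagrad."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Optimizer:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad = np.zeros_like(p.data)

    def clip_grad_norm(self, max_norm: float):
        total = np.sqrt(sum(float(np.sum(p.grad ** 2)) for p in self.params))
        if total > max_norm and total > 0:
            scale = max_norm / total
            for p in self.params:
                p.grad *= scale


class SGD(Optimizer):
    def step(self):
        for p in self.params:
            p.data -= self.lr * p.grad


class RMSProp(Optimizer):
    def __init__(self, params, lr=1e-3, decay=0.9, eps=1e-8):
        super().__init__(params, lr)
        self.decay = decay
        self.eps = eps
        self.cache = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, c in zip(self.params, self.cache):
            c *= self.decay
            c += (1.0 - self.decay) * p.grad ** 2
            p.data -= self.lr * p.grad / (np.sqrt(c) + self.eps)


class Adagrad(Optimizer):
    def __init__(self, params, lr=5e-4, eps=1e-8):
        super().__init__(params, lr)
        self.eps = eps
        self.cache = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, c in zip(self.params, self.cache):
            c += p.grad ** 2
            p.data -= self.lr * p.grad / (np.sqrt(c) + self.eps)
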