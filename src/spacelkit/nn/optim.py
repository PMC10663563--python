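"""Adam and RMSProp over lists of parameter tensors.

Parameters are any objects with ``.data`` and ``.grad`` numpy attributes,
so the same optimizers drive both the network layers and the
Gaussian-process hyperparameters (whose gradients are computed analytically).
"""

from __future__ import annotations

import numpy as np


class _Optimizer:
    def __init__(self, params, lr: float):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        raise NotImplementedError


class Adam(_Optimizer):
    def __init__(self, params, lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSProp(_Optimizer):
    def __init__(self, params, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-8):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.v[i] = self.rho * self.v[i] + (1 - self.rho) * g * g
            p.data = p.data - self.lr * g / (np.sqrt(self.v[i]) + self.eps)
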