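"""Optimizers. AdaGrad is the one the training protocol prescribes."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["AdaGrad"]


class AdaGrad:
    """AdaGrad with per-parameter accumulated squared gradients.

    step: w <- w - lr * g / (sqrt(G) + eps), G accumulating g^2 elementwise.
    """

    def __init__(self, params: list[Tensor], lr: float = 0.001, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.eps = eps
        self._accum = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, acc in zip(self.params, self._accum):
            if p.grad is None:
                continue
            acc += p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(acc) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
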