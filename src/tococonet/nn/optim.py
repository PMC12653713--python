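"""Adam optimizer and reduce-on-plateau learning-rate scheduling."""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["Adam", "ReduceLROnPlateau"]


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay added to the gradient."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class ReduceLROnPlateau:
    """Halve (by ``factor``) the optimizer's learning rate when the monitored
    loss has not improved by at least ``threshold`` for ``patience`` epochs."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 15,
                 threshold: float = 1e-6):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.threshold = threshold
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, value: float) -> None:
        if value < self.best - self.threshold:
            self.best = value
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.optimizer.lr *= self.factor
                self.bad_epochs = 0
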