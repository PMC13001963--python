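"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import numpy as np

from .modules import Parameter

__all__ = ["Adam", "ExponentialDecay", "MilestoneDecay"]


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class ExponentialDecay:
    """Multiplies the optimizer lr by `factor` when stepped (once per epoch)."""

    def __init__(self, optimizer: Adam, factor: float = 0.95):
        self.optimizer = optimizer
        self.factor = factor

    def step(self) -> None:
        self.optimizer.lr *= self.factor


class MilestoneDecay:
    """Multiplies lr by `factor` at each milestone epoch (0-based count of steps)."""

    def __init__(self, optimizer: Adam, milestones: list[int], factor: float = 0.1):
        self.optimizer = optimizer
        self.milestones = set(milestones)
        self.factor = factor
        self.epoch = 0

    def step(self) -> None:
        self.epoch += 1
        if self.epoch in self.milestones:
            self.optimizer.lr *= self.factor
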