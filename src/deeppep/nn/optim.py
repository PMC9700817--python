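"""Adam optimizer and the warmup + cosine learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


def lr_at(step: int, total_steps: int, warmup_steps: int,
          peak_lr: float) -> float:
    """Learning rate under linear warmup followed by cosine decay.

    Ramps linearly from 0 to ``peak_lr`` over ``warmup_steps``, then decays
    as ``peak_lr * 0.5 * (1 + cos(pi * progress))`` so the rate reaches 0 at
    ``total_steps``.  Continuous at the junction and non-negative
    everywhere.
    """
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    if not 0 <= warmup_steps <= total_steps:
        raise ValueError("need 0 <= warmup_steps <= total_steps")
    if step < warmup_steps:
        return peak_lr * step / warmup_steps
    if total_steps == warmup_steps:
        return peak_lr
    progress = (step - warmup_steps) / (total_steps - warmup_steps)
    return peak_lr * 0.5 * (1.0 + np.cos(np.pi * progress))


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
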