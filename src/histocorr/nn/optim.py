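"""SGD with momentum and decoupled-from-nothing (coupled) weight decay,
plus the step learning-rate schedule used by the patch classifier."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "step_lr"]


class SGD:
    """v <- mu*v + (g + wd*p);  p <- p - lr*v  (weight decay folded into the
    gradient before the momentum update, the convention of mainstream DL
    frameworks)."""

    def __init__(self, parameters, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0005):
        self.parameters = list(parameters)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.parameters]

    def step(self):
        for p, v in zip(self.parameters, self._velocity):
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.parameters:
            p.grad[...] = 0.0


def step_lr(lr0: float, epoch: int, milestones=(10, 20), gamma: float = 0.2) -> float:
    """Piecewise-constant schedule: lr0 multiplied by gamma at each milestone.

    With defaults this divides the rate by 5 at epochs 10 and 20:
    0.001 -> 0.0002 -> 0.00004.
    """
    lr = lr0
    for m in milestones:
        if epoch >= m:
            lr *= gamma
    return lr
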