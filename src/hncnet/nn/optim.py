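"""Stochastic gradient descent with classical momentum and L2 weight decay.

Decay is applied to weight matrices only, never to biases; the update is
the standard one: v <- mu*v + (g + l2*w); w <- w - lr*v.
"""

from __future__ import annotations

import numpy as np


class SGD:
    def __init__(self, parameters, lr: float, momentum: float = 0.0, l2: float = 0.0):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.parameters = list(parameters)
        self.lr = lr
        self.momentum = momentum
        self.l2 = l2
        self.velocity = [np.zeros_like(p) for p, _, _ in self.parameters]

    def step(self):
        for (p, g, is_weight), v in zip(self.parameters, self.velocity):
            grad = g + self.l2 * p if (self.l2 and is_weight) else g
            v *= self.momentum
            v += grad
            p -= self.lr * v
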