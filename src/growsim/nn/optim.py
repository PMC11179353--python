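"""Adam optimizer operating on explicit (parameter, gradient) lists."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr=1e-4, betas=(0.0, 0.9), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads):
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for i, (p, g) in enumerate(zip(self.params, grads)):
            if g is None:
                continue
            gd = g.data if hasattr(g, "data") else g
            self.m[i] = b1 * self.m[i] + (1 - b1) * gd
            self.v[i] = b2 * self.v[i] + (1 - b2) * gd * gd
            p.data -= self.lr * (self.m[i] / c1) / (np.sqrt(self.v[i] / c2) + self.eps)
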