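"""AdamW: adaptive moments with decoupled weight decay."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["AdamW"]


class AdamW:
    def __init__(self, params, weight_decay=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params: list[Parameter] = list(params)
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / c1) / (np.sqrt(v / c2) + self.eps)
            if p.decay and self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data = p.data - lr * update
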