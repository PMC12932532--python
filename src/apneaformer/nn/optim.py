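"""AdamW: Adam with decoupled weight decay.

The decay term is applied directly to the parameters (scaled by the current
learning rate), not folded into the gradient, which is what distinguishes
AdamW from L2-regularized Adam. Bias terms and normalization affines are
excluded from decay by convention."""

from __future__ import annotations

import numpy as np

from .layers import Layer

_NO_DECAY = ("b", "bq", "bk", "bv", "bo", "gamma", "beta")


class AdamW:
    def __init__(
        self,
        layers: list[Layer],
        lr: float = 1e-3,
        weight_decay: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]
        self._v = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for layer, m, v in zip(self.layers, self._m, self._v):
            if not layer.trainable:
                continue
            for name, p in layer.params.items():
                g = layer.grads[name]
                m[name] = b1 * m[name] + (1 - b1) * g
                v[name] = b2 * v[name] + (1 - b2) * g * g
                mhat = m[name] / c1
                vhat = v[name] / c2
                update = mhat / (np.sqrt(vhat) + self.eps)
                if self.weight_decay and name not in _NO_DECAY:
                    update = update + self.weight_decay * p
                p -= (self.lr * update).astype(p.dtype)

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()
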