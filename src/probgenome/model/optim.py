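"""AdamW optimizer (decoupled weight decay).

Defaults follow the pretraining recipe: beta1=0.9, beta2=0.99, eps=1e-8,
weight decay 0.01. Decay applies only to matrix-shaped weights; biases
and layer-norm gains are exempt, the standard convention for
transformer training.
"""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class AdamW:
    def __init__(self, params: list[Parameter], lr: float = 4e-4,
                 betas: tuple[float, float] = (0.9, 0.99),
                 eps: float = 1e-8, weight_decay: float = 0.01) -> None:
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        # moments kept in float64 regardless of model compute dtype
        self._m = [np.zeros(p.value.shape, dtype=np.float64)
                   for p in self.params]
        self._v = [np.zeros(p.value.shape, dtype=np.float64)
                   for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad.astype(np.float64, copy=False)
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and p.value.ndim >= 2:
                p.value -= (self.lr * self.weight_decay
                            * p.value).astype(p.value.dtype)
            p.value -= (self.lr * update).astype(p.value.dtype)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self._m],
            "v": [v.copy() for v in self._v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        if len(state["m"]) != len(self.params):
            raise ValueError("optimizer state does not match parameter list")
        self._m = [np.asarray(m, dtype=np.float64) for m in state["m"]]
        self._v = [np.asarray(v, dtype=np.float64) for v in state["v"]]


def clip_gradients(params: list[Parameter], max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``;
    returns the pre-clip norm."""
    total = 0.0
    for p in params:
        if p.trainable:
            total += float((p.grad * p.grad).sum())
    norm = total ** 0.5
    if norm > max_norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.trainable:
                p.grad *= scale
    return norm
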