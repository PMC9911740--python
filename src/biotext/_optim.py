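"""Minimal Adam optimizer over named NumPy parameter arrays."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999, eps=1e-8).

    Parameters are a dict name -> ndarray, updated in place.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient for {k!r}")
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                # decoupled (AdamW-style) decay
                self.params[k] -= self.lr * self.weight_decay * self.params[k]
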