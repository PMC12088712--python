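"""Adam optimizer over the Module parameter registry."""
from __future__ import annotations

import numpy as np

from .layers import Module


class Adam:
    def __init__(self, model: Module, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        for path, mod in model.named_parameters():
            leaf = path.rsplit(".", 1)[-1]
            self._m[path] = np.zeros_like(mod.params[leaf])
            self._v[path] = np.zeros_like(mod.params[leaf])

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for path, mod in self.model.named_parameters():
            leaf = path.rsplit(".", 1)[-1]
            g = mod.grads[leaf]
            m, v = self._m[path], self._v[path]
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mod.params[leaf] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
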