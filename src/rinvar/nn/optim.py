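"""Adadelta optimizer (accumulated-gradient / accumulated-update form)."""

from __future__ import annotations

import numpy as np


class Adadelta:
    """Adadelta with the classic unit base step.

    Per parameter x with gradient g:

        E[g^2]  <- rho E[g^2] + (1 - rho) g^2
        delta   =  -sqrt(E[dx^2] + eps) / sqrt(E[g^2] + eps) * g
        E[dx^2] <- rho E[dx^2] + (1 - rho) delta^2
        x       <- x + lr * delta

    The method adapts its own effective step size, so ``lr`` stays at the
    original 1.0; ``rho`` and ``eps`` follow the original formulation.
    """

    def __init__(self, lr: float = 1.0, rho: float = 0.95, eps: float = 1e-6) -> None:
        self.lr, self.rho, self.eps = lr, rho, eps
        self._eg: dict[str, np.ndarray] = {}
        self._ed: dict[str, np.ndarray] = {}

    def step(self, parameters) -> None:
        """Apply one update; ``parameters`` yields (key, layer, name, array)."""
        for key, layer, name, arr in parameters:
            g = layer.grads.get(name)
            if g is None:
                continue
            if key not in self._eg:
                self._eg[key] = np.zeros_like(arr)
                self._ed[key] = np.zeros_like(arr)
            eg, ed = self._eg[key], self._ed[key]
            eg *= self.rho
            eg += (1 - self.rho) * g * g
            delta = -np.sqrt(ed + self.eps) / np.sqrt(eg + self.eps) * g
            ed *= self.rho
            ed += (1 - self.rho) * delta * delta
            layer.params[name] = arr + self.lr * delta
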