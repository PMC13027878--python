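"""AdamW with decoupled weight decay, and an exponential moving average of weights."""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

from srcorrect.errors import ConfigurationError
from srcorrect.nn.layers import Parameter


class AdamW:
    """Adam with decoupled weight decay (decay applied to weights, not grads)."""

    def __init__(self, params: list[Parameter], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        if lr <= 0:
            raise ConfigurationError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self._v = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            if self.weight_decay:
                p.data = p.data - self.lr * self.weight_decay * p.data
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def ema_update(ema_weights: dict[str, np.ndarray], weights: dict[str, np.ndarray],
               decay: float) -> dict[str, np.ndarray]:
    """One EMA step per parameter: ema <- decay*ema + (1-decay)*w."""
    if set(ema_weights) != set(weights):
        raise ConfigurationError("EMA and model parameter sets do not match")
    return {k: decay * ema_weights[k] + (1.0 - decay) * weights[k] for k in weights}


class EMA:
    """Exponential moving average of a model's parameters.

    The shadow copy never receives gradients; ``swapped_in`` temporarily
    installs it into the model for (validation) inference.
    """

    def __init__(self, model, decay: float):
        if not 0 < decay < 1:
            raise ConfigurationError("EMA decay must be in (0, 1)")
        self.decay = decay
        self._model = model
        self.shadow = {k: p.data.copy() for k, p in model.named_parameters()}

    def update(self) -> None:
        for k, p in self._model.named_parameters():
            self.shadow[k] = self.decay * self.shadow[k] + (1.0 - self.decay) * p.data

    @contextmanager
    def swapped_in(self):
        backup = {k: p.data for k, p in self._model.named_parameters()}
        for k, p in self._model.named_parameters():
            p.data = self.shadow[k].astype(p.data.dtype)
        try:
            yield
        finally:
            for k, p in self._model.named_parameters():
                p.data = backup[k]

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.shadow.items()}
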