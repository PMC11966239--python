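"""First-order optimizers for the numpy parameter dictionaries."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW"]


class AdamW:
    """AdamW with optional per-parameter learning rates.

    ``lr`` and ``weight_decay`` may be scalars or dicts mapping parameter
    names to values (missing names fall back to ``default_lr`` / zero
    decay).  Updates are applied in place so shared parameter references
    stay valid.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float | dict[str, float] = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float | dict[str, float] = 0.0,
        default_lr: float = 1e-3,
    ):
        self.params = params
        if isinstance(lr, dict):
            self.lr = {k: lr.get(k, default_lr) for k in params}
        else:
            self.lr = {k: lr for k in params}
        if isinstance(weight_decay, dict):
            self.weight_decay = {k: weight_decay.get(k, 0.0) for k in params}
        else:
            self.weight_decay = {k: weight_decay for k in params}
        self.b1, self.b2 = betas
        self.eps = eps
        self._base_lr = dict(self.lr)
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def set_lr_scale(self, scale: float) -> None:
        """Scale all learning rates relative to their construction values."""
        self.lr = {k: v * scale for k, v in self._base_lr.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            if self.weight_decay[k]:
                p -= self.lr[k] * self.weight_decay[k] * p
            p -= self.lr[k] * mhat / (np.sqrt(vhat) + self.eps)
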