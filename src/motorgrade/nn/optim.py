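"""Adam optimizer and a one-cycle learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Adam:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.99),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float | None = None) -> None:
        if lr is not None:
            self.lr = lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * p.grad
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * p.grad**2
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def one_cycle_lr(
    step: int,
    total_steps: int,
    max_lr: float,
    pct_start: float = 0.25,
    div_start: float = 25.0,
    div_final: float = 1e4,
) -> float:
    """Cosine-annealed one-cycle schedule: warm up to max_lr, anneal down.

    `step` is 0-based; the peak sits at pct_start * total_steps.
    """
    if total_steps <= 1:
        return max_lr
    up = max(1, int(round(pct_start * total_steps)))
    if step < up:
        frac = step / up
        lo = max_lr / div_start
        return lo + (max_lr - lo) * 0.5 * (1 - np.cos(np.pi * frac))
    frac = (step - up) / max(1, total_steps - up)
    lo = max_lr / div_final
    return lo + (max_lr - lo) * 0.5 * (1 + np.cos(np.pi * min(frac, 1.0)))
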