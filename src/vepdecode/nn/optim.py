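"""AdamW optimiser and one-cycle learning-rate schedule."""

from __future__ import annotations

import numpy as np


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay is applied only to parameters with ``ndim > 1`` (matrices and
    convolution kernels), never to biases or normalisation affine terms.
    """

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            if self.weight_decay and p.data.ndim > 1:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def one_cycle_lr(step: int, total_steps: int, max_lr: float, *,
                 warmup_frac: float = 0.3, div_factor: float = 25.0,
                 final_div_factor: float = 1e4) -> float:
    """Closed-form one-cycle schedule value at ``step`` (0-based).

    Cosine warm-up from ``max_lr / div_factor`` to ``max_lr`` over the first
    ``warmup_frac`` of training, then cosine annealing down to
    ``max_lr / final_div_factor``.
    """
    if total_steps <= 1:
        return max_lr
    warm = max(int(round(warmup_frac * total_steps)), 1)
    lo, hi = max_lr / div_factor, max_lr
    end = max_lr / final_div_factor
    if step < warm:
        frac = step / max(warm - 1, 1)
        return lo + (hi - lo) * 0.5 * (1 - np.cos(np.pi * frac))
    frac = (step - warm) / max(total_steps - warm - 1, 1)
    return end + (hi - end) * 0.5 * (1 + np.cos(np.pi * min(frac, 1.0)))
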