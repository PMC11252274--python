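"""Forward-process noise schedule for the latent diffusion model."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class DiffusionSchedule:
    """Variances beta_t of the T forward noising steps, t = 1..T.

    ``alpha_bar[t-1]`` is the cumulative signal fraction after t steps:
    z_t = sqrt(alpha_bar_t) z_0 + sqrt(1 - alpha_bar_t) eps.
    """

    betas: np.ndarray
    alpha_bar: np.ndarray = field(init=False)

    def __post_init__(self):
        betas = np.asarray(self.betas, dtype=np.float64)
        if np.any(betas <= 0) or np.any(betas >= 1):
            raise ValueError("betas must lie in (0, 1)")
        ab = np.cumprod(1.0 - betas)
        if not (np.all(np.diff(ab) < 0) and np.all(ab > 0) and np.all(ab <= 1)):
            raise ValueError("alpha_bar must be strictly decreasing in (0, 1]")
        object.__setattr__(self, "betas", betas)
        object.__setattr__(self, "alpha_bar", ab)

    @property
    def T(self) -> int:
        return len(self.betas)

    def alpha_bar_at(self, t) -> np.ndarray:
        """alpha_bar for step index t in 1..T; t = 0 means 'no noise' (1.0)."""
        t = np.asarray(t)
        out = np.where(t > 0, self.alpha_bar[np.maximum(t - 1, 0)], 1.0)
        return out

    @classmethod
    def linear(cls, T: int = 1000, beta_start: float = 1e-4,
               beta_end: float = 2e-2) -> "DiffusionSchedule":
        return cls(betas=np.linspace(beta_start, beta_end, T))
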