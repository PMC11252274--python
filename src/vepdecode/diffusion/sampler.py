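"""Deterministic PLMS (pseudo linear multi-step) sampling.

The sampler walks a decreasing sub-sequence of diffusion steps.  Until four
noise evaluations are buffered it uses lower-order pseudo-multistep updates
(a two-evaluation pseudo-Heun start, then 2nd/3rd-order Adams–Bashforth
forms); from the fourth step on it applies the 4th-order linear multi-step
combination (55 e - 59 e1 + 37 e2 - 9 e3) / 24.
"""

from __future__ import annotations

import numpy as np

from .. import nn
from ..nn import Tensor
from .schedule import DiffusionSchedule
from .unet import ConditionedUNet


def _x_prev(x: np.ndarray, e: np.ndarray, ab_t: float, ab_prev: float,
            clip_x0: float | None = None) -> np.ndarray:
    """Transfer x from noise level ab_t to ab_prev using noise estimate e.

    ``clip_x0`` saturates the implied clean-latent prediction at +-clip_x0;
    at very low alpha_bar the division by sqrt(alpha_bar) amplifies model
    error enormously, and bounding x0 to the data range keeps a small,
    imperfect denoiser's trajectory on scale.
    """
    x0 = (x - np.sqrt(1.0 - ab_t) * e) / np.sqrt(ab_t)
    if clip_x0 is not None:
        np.clip(x0, -clip_x0, clip_x0, out=x0)
    return np.sqrt(ab_prev) * x0 + np.sqrt(1.0 - ab_prev) * e


def plms_timesteps(T: int, steps: int) -> np.ndarray:
    """Decreasing step indices t in 1..T (length ``steps``)."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if steps > T:
        raise ValueError("steps cannot exceed the schedule length T")
    ts = np.unique(np.linspace(1, T, steps).round().astype(int))[::-1]
    return ts


def sample_plms(model: ConditionedUNet, schedule: DiffusionSchedule,
                embeddings: np.ndarray | None, shape: tuple, steps: int,
                seed: int, double: bool = True,
                decoder=None, clip_x0: float | None = None) -> np.ndarray:
    """Generate latents (or images, when a decoder is given) from embeddings.

    Deterministic given (weights, embeddings, seed, steps).  ``shape`` is the
    per-sample latent shape (c, h, w); one sample per embedding row.
    """
    model.eval()
    rng = np.random.default_rng(seed)
    B = 1 if embeddings is None else len(embeddings)
    x = rng.standard_normal((B, *shape)).astype(nn.DTYPE)
    y = None if embeddings is None else np.asarray(embeddings, dtype=nn.DTYPE)
    ts = plms_timesteps(schedule.T, steps)
    ab = schedule.alpha_bar_at(ts).astype(np.float64)
    ab_next = np.append(ab[1:], 1.0)        # t -> 0 means fully denoised

    def eps(xa: np.ndarray, t_scalar: int) -> np.ndarray:
        with nn.no_grad():
            yy = None if y is None else Tensor(y)
            t_arr = np.full(len(xa), t_scalar, dtype=int)
            return model(Tensor(xa), t_arr, yy, double=double).data

    old_eps: list[np.ndarray] = []
    for i, t in enumerate(ts):
        e_t = eps(x, int(t))
        if len(old_eps) == 0:
            # pseudo-Heun: average the slope at t and at the predicted t_prev
            x_mid = _x_prev(x, e_t, ab[i], ab_next[i], clip_x0)
            t_next = int(ts[i + 1]) if i + 1 < len(ts) else 0
            e_next = eps(x_mid, max(t_next, 1)) if t_next > 0 else e_t
            e_prime = 0.5 * (e_t + e_next)
        elif len(old_eps) == 1:
            e_prime = (3.0 * e_t - old_eps[-1]) / 2.0
        elif len(old_eps) == 2:
            e_prime = (23.0 * e_t - 16.0 * old_eps[-1]
                       + 5.0 * old_eps[-2]) / 12.0
        else:
            e_prime = (55.0 * e_t - 59.0 * old_eps[-1] + 37.0 * old_eps[-2]
                       - 9.0 * old_eps[-3]) / 24.0
        old_eps.append(e_t)
        if len(old_eps) > 3:
            old_eps.pop(0)
        x = _x_prev(x, e_prime.astype(np.float64), ab[i], ab_next[i],
                    clip_x0).astype(nn.DTYPE)
    if decoder is not None:
        return decoder.decode(x)
    return x
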