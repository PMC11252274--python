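"""Diffusion objective and (pre)training loop for the latent denoiser."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import nn
from ..nn import Tensor
from .schedule import DiffusionSchedule
from .unet import ConditionedUNet


def diffusion_loss(latents: np.ndarray, embeddings: np.ndarray | None,
                   model: ConditionedUNet, schedule: DiffusionSchedule,
                   rng: np.random.Generator, double: bool = True) -> Tensor:
    """Denoising-score-matching objective.

    Draws t ~ U{1..T} and eps ~ N(0, I), forms
    z_t = sqrt(alpha_bar_t) z_0 + sqrt(1 - alpha_bar_t) eps and returns the
    mean squared error || eps - eps_theta(z_t, t, tau(y), sigma(tau(y))) ||^2
    (the sigma pathway is disabled when ``double`` is False, giving the
    single-conditioning objective).
    """
    z0 = np.asarray(latents, dtype=nn.DTYPE)
    B = len(z0)
    t = rng.integers(1, schedule.T + 1, size=B)
    eps = rng.standard_normal(z0.shape).astype(nn.DTYPE)
    ab = schedule.alpha_bar_at(t).astype(nn.DTYPE)[:, None, None, None]
    z_t = np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * eps
    y = None if embeddings is None else Tensor(
        np.asarray(embeddings, dtype=nn.DTYPE))
    pred = model(Tensor(z_t), t, y, double=double)
    return ((pred - Tensor(eps)) ** 2).mean()


@dataclass
class DiffusionTrainConfig:
    epochs: int = 40
    batch_size: int = 64
    lr: float = 1e-3
    weight_decay: float = 1e-4
    seed: int = 0


def train_denoiser(model: ConditionedUNet, latents: np.ndarray,
                   schedule: DiffusionSchedule,
                   cfg: DiffusionTrainConfig,
                   embeddings: np.ndarray | None = None,
                   double: bool = True) -> list[float]:
    """Train eps_theta on latents (unconditional when ``embeddings`` is None);
    returns the per-epoch loss history."""
    rng = np.random.default_rng(cfg.seed)
    model.seed_rng(cfg.seed + 1)
    opt = nn.AdamW(model.parameters(), lr=cfg.lr,
                   weight_decay=cfg.weight_decay)
    n = len(latents)
    history = []
    for _ in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            emb = None if embeddings is None else embeddings[idx]
            loss = diffusion_loss(latents[idx], emb, model, schedule, rng,
                                  double=double)
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    return history
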