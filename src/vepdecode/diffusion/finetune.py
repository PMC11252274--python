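"""Selective fine-tuning of the reconstruction stack.

Only the EEG encoder, the cross-attention weights (W_Q, W_K, W_V and their
output projections) and the two conditioning projectors (tau, sigma) are
updated; the UNet backbone and the latent autoencoder stay frozen — the
freeze contract is bitwise and is asserted by the test-suite.

Two practical elements make the alignment between the EEG embedding space
and the pretrained conditioning space learnable at desk scale:

* embeddings are standardised (per-dimension z-score over the fine-tuning
  pairs) before entering tau, matching the unit-scale conditioning
  vectors used during pretraining; the affine is frozen into the result
  and must be applied at inference time too;
* Gaussian noise is added to the standardised embeddings during training
  (an augmentation that forces the attention weights to key on the class-
  level structure rather than memorising individual trial vectors), and
  the encoder itself moves with a much smaller learning rate than the
  attention/projector weights so its pretrained class structure survives.

The reference training procedure uses a 5e-6 learning rate over 200
epochs; the desk-scale defaults here are larger/shorter and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import nn
from ..models import ModelHandle, extract_embedding
from ..nn import Tensor
from ..preprocessing import EpochSet
from .schedule import DiffusionSchedule
from .unet import ConditionedUNet

PAPER_FINETUNE_LR = 5e-6
PAPER_FINETUNE_EPOCHS = 200


@dataclass
class FinetuneConfig:
    lr: float = 5e-4                 # attention + projectors (desk scale)
    encoder_lr: float = 2e-5         # encoder crawls to preserve its classes
    epochs: int = 8                  # desk scale; reference value is 200
    batch_size: int = 128
    weight_decay: float = 0.0
    embedding_noise_sd: float = 0.5
    standardize_embeddings: bool = True
    max_pairs: int | None = None     # subsample the pair set for speed
    seed: int = 0
    double: bool = True


@dataclass
class FinetuneResult:
    encoder: ModelHandle
    unet: ConditionedUNet
    embed_mu: np.ndarray
    embed_sd: np.ndarray
    history: list = field(default_factory=list)
    trainable_names: list = field(default_factory=list)

    def conditioning_embeddings(self, epochs_or_array) -> np.ndarray:
        """Standardised embeddings ready to condition the sampler."""
        emb = extract_embedding(self.encoder, epochs_or_array)
        return ((emb - self.embed_mu) / self.embed_sd).astype(nn.DTYPE)


def trainable_finetune_parameters(encoder: ModelHandle, unet: ConditionedUNet
                                  ) -> dict[str, nn.Parameter]:
    """The declared trainable set: encoder + tau/sigma + cross-attention."""
    params = {f"encoder.{k}": p for k, p in encoder.network.named_parameters()}
    for mod_name, mod in unet.conditioning_modules().items():
        for k, p in mod.named_parameters():
            params[f"unet.{mod_name}.{k}"] = p
    return params


def finetune(encoder: ModelHandle, unet: ConditionedUNet,
             schedule: DiffusionSchedule, epochs: EpochSet,
             latents_by_trial: np.ndarray,
             cfg: FinetuneConfig | None = None) -> FinetuneResult:
    """Fine-tune on (EEG trial, image latent) pairs with the conditional
    denoising objective (double conditioning by default).

    ``latents_by_trial`` holds the latent of the stimulus image shown in
    each retained trial, aligned with ``epochs.retained_data()``.
    """
    cfg = cfg or FinetuneConfig()
    if not encoder.is_encoder:
        raise ValueError("fine-tuning requires an EEGNet+ encoder handle")
    x = np.asarray(epochs.retained_data(), dtype=nn.DTYPE)
    z0 = np.asarray(latents_by_trial, dtype=nn.DTYPE)
    if len(x) != len(z0):
        raise ValueError("one latent per retained trial required")
    params = trainable_finetune_parameters(encoder, unet)
    if not params:
        raise ValueError("trainable set is empty")
    # freeze everything, then re-enable the declared set
    for p in unet.parameters():
        p.requires_grad = False
    for p in params.values():
        p.requires_grad = True

    rng = np.random.default_rng(cfg.seed)
    if cfg.max_pairs is not None and len(x) > cfg.max_pairs:
        pick = rng.choice(len(x), cfg.max_pairs, replace=False)
        x, z0 = x[pick], z0[pick]

    emb0 = extract_embedding(encoder, x)
    if cfg.standardize_embeddings:
        mu = emb0.mean(axis=0)
        sd = emb0.std(axis=0) + 1e-6
    else:
        mu = np.zeros(emb0.shape[1], dtype=nn.DTYPE)
        sd = np.ones(emb0.shape[1], dtype=nn.DTYPE)
    mu_t = Tensor(mu.astype(nn.DTYPE))
    sd_t = Tensor(sd.astype(nn.DTYPE))

    encoder.network.seed_rng(cfg.seed + 1)
    unet.seed_rng(cfg.seed + 2)
    cond = [p for name, p in params.items() if name.startswith("unet.")]
    enc_p = [p for name, p in params.items() if name.startswith("encoder.")]
    opt_cond = nn.AdamW(cond, lr=cfg.lr, weight_decay=cfg.weight_decay)
    opt_enc = nn.AdamW(enc_p, lr=cfg.encoder_lr,
                       weight_decay=cfg.weight_decay)
    n = len(x)
    history = []
    for _ in range(cfg.epochs):
        encoder.network.train()
        unet.train()
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            emb = encoder.network(Tensor(x[idx, None, :, :]),
                                  encoder_mode=True)
            emb = (emb - mu_t) / sd_t
            if cfg.embedding_noise_sd > 0:
                emb = emb + Tensor(
                    cfg.embedding_noise_sd
                    * rng.standard_normal(emb.shape).astype(nn.DTYPE))
            B = len(idx)
            t = rng.integers(1, schedule.T + 1, size=B)
            eps = rng.standard_normal(z0[idx].shape).astype(nn.DTYPE)
            ab = schedule.alpha_bar_at(t).astype(nn.DTYPE)[:, None, None, None]
            z_t = np.sqrt(ab) * z0[idx] + np.sqrt(1.0 - ab) * eps
            pred = unet(Tensor(z_t), t, emb, double=cfg.double)
            loss = ((pred - Tensor(eps)) ** 2).mean()
            encoder.network.zero_grad()
            unet.zero_grad()
            loss.backward()
            opt_cond.step()
            opt_enc.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    for p in unet.parameters():
        p.requires_grad = True
    encoder.eval()
    unet.eval()
    return FinetuneResult(encoder=encoder, unet=unet, embed_mu=mu,
                          embed_sd=sd, history=history,
                          trainable_names=sorted(params.keys()))
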