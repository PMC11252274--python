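"""Conditioned UNet denoiser with cross-attention and time-step conditioning.

The denoiser eps_theta(z_t, t, tau(y), sigma(tau(y))) predicts the noise in a
latent.  Conditioning enters in two ways ("double conditioning"):

* cross-attention — the projected EEG embedding tau(y) (M tokens of depth
  d_tau) supplies keys and values; queries come from intermediate feature
  maps phi_i(z_t):  Attention(Q, K, V) = softmax(Q K^T / sqrt(d_k)) V with
  Q = W_Q phi_i(z_t), K = W_K tau(y), V = W_V tau(y);
* time-step conditioning — sigma(tau(y)) (1 x d_t) is added to the sinusoidal
  time embedding.

A ``double=False`` forward disables the sigma pathway (single conditioning).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import nn
from ..nn import Tensor


def timestep_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Sinusoidal embedding of integer diffusion steps, shape (B, dim)."""
    t = np.asarray(t, dtype=np.float64).reshape(-1)
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((len(t), 1))], axis=1)
    return emb.astype(nn.DTYPE)


def cross_attention(queries: Tensor, context: Tensor,
                    w_q: Tensor, w_k: Tensor, w_v: Tensor) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V with Q/K/V formed by the given weights.

    ``queries``: (B, Nq, d) intermediate features; ``context``: (B, M, d_tau)
    conditioning tokens; weight shapes (d, d_k), (d_tau, d_k), (d_tau, d_k).
    """
    q = nn.matmul(queries, w_q)
    k = nn.matmul(context, w_k)
    v = nn.matmul(context, w_v)
    d_k = q.shape[-1]
    scores = nn.matmul(q, k.transpose(0, 2, 1)) * (1.0 / np.sqrt(d_k))
    attn = nn.softmax(scores, axis=-1)
    return nn.matmul(attn, v)


class CrossAttentionBlock(nn.Module):
    """Residual single-head cross-attention over a feature map."""

    def __init__(self, channels: int, d_tau: int, d_k: int, rng):
        super().__init__()
        lim_q = np.sqrt(6.0 / (channels + d_k))
        lim_kv = np.sqrt(6.0 / (d_tau + d_k))
        self.w_q = nn.Parameter(rng.uniform(-lim_q, lim_q, (channels, d_k)))
        self.w_k = nn.Parameter(rng.uniform(-lim_kv, lim_kv, (d_tau, d_k)))
        self.w_v = nn.Parameter(rng.uniform(-lim_kv, lim_kv, (d_tau, d_k)))
        self.proj_out = nn.Linear(d_k, channels, rng)
        self.norm = nn.GroupNorm(8, channels)

    def forward(self, x: Tensor, context: Tensor) -> Tensor:
        B, C, H, W = x.shape
        h = self.norm(x)
        q = h.reshape(B, C, H * W).transpose(0, 2, 1)        # (B, Nq, C)
        attended = cross_attention(q, context, self.w_q, self.w_k, self.w_v)
        out = self.proj_out(attended)                        # (B, Nq, C)
        return x + out.transpose(0, 2, 1).reshape(B, C, H, W)


class TauProjector(nn.Module):
    """tau_theta: 512-d embedding -> M tokens of depth d_tau via a 1x1 conv."""

    def __init__(self, embed_dim: int, m_tokens: int, d_tau: int, rng):
        super().__init__()
        if embed_dim % m_tokens:
            raise ValueError("embed_dim must be divisible by m_tokens")
        self.m_tokens = m_tokens
        self.token_depth = embed_dim // m_tokens
        self.conv = nn.Conv2d(self.token_depth, d_tau, (1, 1), rng)

    def forward(self, y: Tensor) -> Tensor:
        B = y.shape[0]
        tokens = y.reshape(B, self.m_tokens, self.token_depth)
        h = tokens.transpose(0, 2, 1).reshape(B, self.token_depth, 1,
                                              self.m_tokens)
        h = self.conv(h)                                     # (B, d_tau, 1, M)
        return h.reshape(B, h.shape[1], self.m_tokens).transpose(0, 2, 1)


class SigmaProjector(nn.Module):
    """sigma_theta: tau(y) tokens -> a single d_t vector added to the time
    embedding."""

    def __init__(self, m_tokens: int, d_tau: int, d_time: int, rng):
        super().__init__()
        self.lin = nn.Linear(m_tokens * d_tau, d_time, rng)

    def forward(self, tokens: Tensor) -> Tensor:
        B, M, D = tokens.shape
        return self.lin(tokens.reshape(B, M * D))


class ResBlock(nn.Module):
    def __init__(self, c_in: int, c_out: int, d_time: int, rng):
        super().__init__()
        self.norm1 = nn.GroupNorm(8, c_in)
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng, padding="same")
        self.temb = nn.Linear(d_time, c_out, rng)
        self.norm2 = nn.GroupNorm(8, c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng, padding="same")
        self.skip = nn.Conv2d(c_in, c_out, (1, 1), rng) if c_in != c_out else None

    def forward(self, x: Tensor, temb: Tensor) -> Tensor:
        h = self.conv1(self.norm1(x).silu())
        t = self.temb(temb.silu())
        h = h + t.reshape(t.shape[0], t.shape[1], 1, 1)
        h = self.conv2(self.norm2(h).silu())
        return h + (self.skip(x) if self.skip is not None else x)


@dataclass
class UNetConfig:
    latent_channels: int = 4
    base_channels: int = 32
    d_tau: int = 64
    d_k: int = 64
    m_tokens: int = 4
    d_time: int = 64
    embed_dim: int = 512


class ConditionedUNet(nn.Module):
    """Two-level UNet over c x 16 x 16 latents with cross-attention at the
    8 x 8 resolution and in the middle block."""

    def __init__(self, cfg: UNetConfig, rng: np.random.Generator):
        super().__init__()
        c1, c2 = cfg.base_channels, 2 * cfg.base_channels
        self.cfg = cfg
        self.tau = TauProjector(cfg.embed_dim, cfg.m_tokens, cfg.d_tau, rng)
        self.sigma = SigmaProjector(cfg.m_tokens, cfg.d_tau, cfg.d_time, rng)
        self.time_lin1 = nn.Linear(cfg.d_time, cfg.d_time, rng)
        self.time_lin2 = nn.Linear(cfg.d_time, cfg.d_time, rng)
        self.conv_in = nn.Conv2d(cfg.latent_channels, c1, 3, rng, padding="same")
        self.down_block = ResBlock(c1, c1, cfg.d_time, rng)
        self.downsample = nn.Conv2d(c1, c2, 3, rng, stride=2, padding="same")
        self.mid_block1 = ResBlock(c2, c2, cfg.d_time, rng)
        self.mid_attn = CrossAttentionBlock(c2, cfg.d_tau, cfg.d_k, rng)
        self.mid_block2 = ResBlock(c2, c2, cfg.d_time, rng)
        self.up_block = ResBlock(c1 + c2, c1, cfg.d_time, rng)
        self.up_attn = CrossAttentionBlock(c1, cfg.d_tau, cfg.d_k, rng)
        self.norm_out = nn.GroupNorm(8, c1)
        self.conv_out = nn.Conv2d(c1, cfg.latent_channels, 3, rng, padding="same")

    def conditioning_modules(self) -> dict[str, nn.Module]:
        """The modules updated during fine-tuning (projectors + attention)."""
        return {"tau": self.tau, "sigma": self.sigma,
                "mid_attn": self.mid_attn, "up_attn": self.up_attn}

    def forward(self, z_t: Tensor, t: np.ndarray, y: Tensor | None,
                double: bool = True) -> Tensor:
        cfg = self.cfg
        if y is None:
            y = Tensor(np.zeros((z_t.shape[0], cfg.embed_dim), dtype=nn.DTYPE))
        tokens = self.tau(y)
        temb = Tensor(timestep_embedding(t, cfg.d_time))
        temb = self.time_lin2(self.time_lin1(temb).silu())
        if double:
            temb = temb + self.sigma(tokens)
        h1 = self.conv_in(z_t)
        h1 = self.down_block(h1, temb)
        h2 = self.downsample(h1)
        h2 = self.mid_block1(h2, temb)
        h2 = self.mid_attn(h2, tokens)
        h2 = self.mid_block2(h2, temb)
        up = nn.upsample2x_nearest(h2)
        h = nn.concat([up, h1], axis=1)
        h = self.up_block(h, temb)
        h = self.up_attn(h, tokens)
        return self.conv_out(self.norm_out(h).silu())
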