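"""Small convolutional latent autoencoder (the image codec for the LDM).

Maps 3 x S x S images to a c x S/4 x S/4 latent (compression factor 12 for
the default 4-channel latent) and back.  The default codec is a plain
autoencoder; a small-codebook vector-quantised variant can be enabled in the
config.  Latents are rescaled to roughly unit variance before entering the
diffusion model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import nn
from ..nn import Tensor


@dataclass
class AutoencoderConfig:
    latent_channels: int = 4
    base_channels: int = 32
    vq: bool = False
    codebook_size: int = 64
    commitment_weight: float = 0.25
    epochs: int = 60
    batch_size: int = 64
    lr: float = 2e-3
    holdout_frac: float = 0.1
    max_holdout_mse: float = 0.02    # divergence guard on held-out images
    seed: int = 0


class _Encoder(nn.Module):
    def __init__(self, cfg: AutoencoderConfig, rng):
        super().__init__()
        c = cfg.base_channels
        self.c1 = nn.Conv2d(3, c, 3, rng, stride=2, padding="same")
        self.c2 = nn.Conv2d(c, 2 * c, 3, rng, stride=2, padding="same")
        self.c3 = nn.Conv2d(2 * c, cfg.latent_channels, 3, rng, padding="same")

    def forward(self, x):
        return self.c3(self.c2(self.c1(x).silu()).silu())


class _Decoder(nn.Module):
    def __init__(self, cfg: AutoencoderConfig, rng):
        super().__init__()
        c = cfg.base_channels
        self.c1 = nn.Conv2d(cfg.latent_channels, 2 * c, 3, rng, padding="same")
        self.c2 = nn.Conv2d(2 * c, c, 3, rng, padding="same")
        self.c3 = nn.Conv2d(c, 3, 3, rng, padding="same")

    def forward(self, z):
        h = nn.upsample2x_nearest(self.c1(z).silu())
        h = nn.upsample2x_nearest(self.c2(h).silu())
        return self.c3(h).sigmoid()


class AutoencoderNet(nn.Module):
    def __init__(self, cfg: AutoencoderConfig, rng):
        super().__init__()
        self.encoder = _Encoder(cfg, rng)
        self.decoder = _Decoder(cfg, rng)
        if cfg.vq:
            self.codebook = nn.Parameter(
                0.5 * rng.standard_normal((cfg.codebook_size, cfg.latent_channels)))
        self.cfg = cfg

    def quantize(self, z: Tensor) -> tuple[Tensor, Tensor, np.ndarray]:
        """Nearest-codebook quantisation with a straight-through estimator.

        Returns (quantised-with-ST-gradient, codebook/commitment loss, codes).
        """
        B, C, H, W = z.shape
        flat = z.data.transpose(0, 2, 3, 1).reshape(-1, C)
        cb = self.codebook.data
        d = ((flat[:, None, :] - cb[None, :, :]) ** 2).sum(-1)
        codes = d.argmin(axis=1)
        zq_data = cb[codes].reshape(B, H, W, C).transpose(0, 3, 1, 2) \
            .astype(z.dtype)
        # straight-through: forward value is z_q, gradient flows to z
        st = z + (Tensor(zq_data) - z.detach())
        # codebook loss pulls selected entries toward the (frozen) encoder
        # output; commitment loss pulls the encoder toward its codes
        gathered = _gather_codebook(self.codebook, codes, (B, C, H, W))
        cb_loss = ((gathered - Tensor(z.data)) ** 2).mean()
        commit = ((z - Tensor(zq_data)) ** 2).mean()
        loss = cb_loss + self.cfg.commitment_weight * commit
        return st, loss, codes.reshape(B, H, W)

    def forward(self, x, return_latent: bool = False):
        z = self.encoder(x)
        aux = None
        if self.cfg.vq:
            z, aux, _ = self.quantize(z)
        recon = self.decoder(z)
        if return_latent:
            return recon, z, aux
        return recon


def _gather_codebook(codebook: nn.Parameter, codes: np.ndarray,
                     shape: tuple) -> Tensor:
    """Differentiable gather of codebook rows (gradient scatters back)."""
    B, C, H, W = shape

    out_data = codebook.data[codes].reshape(B, H, W, C).transpose(0, 3, 1, 2)

    def bwd(g):
        gflat = g.transpose(0, 2, 3, 1).reshape(-1, C)
        acc = np.zeros_like(codebook.data)
        np.add.at(acc, codes, gflat)
        codebook._accumulate(acc)
    return Tensor._make(out_data.astype(codebook.data.dtype), (codebook,), bwd)


@dataclass
class LatentAutoencoder:
    """Trained codec with numpy-facing encode/decode plus latent rescaling."""

    net: AutoencoderNet
    latent_scale: float = 1.0
    history: list = field(default_factory=list)

    def encode(self, images: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """images (N, S, S, 3) in [0,1] -> latents (N, c, S/4, S/4)."""
        self.net.eval()
        out = []
        with nn.no_grad():
            for i in range(0, len(images), batch_size):
                x = Tensor(np.transpose(images[i:i + batch_size], (0, 3, 1, 2))
                           .astype(nn.DTYPE))
                z = self.net.encoder(x)
                if self.net.cfg.vq:
                    z, _, _ = self.net.quantize(z)
                out.append(z.data / self.latent_scale)
        return np.concatenate(out)

    def decode(self, latents: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """latents -> images (N, S, S, 3) in [0,1]."""
        self.net.eval()
        out = []
        with nn.no_grad():
            for i in range(0, len(latents), batch_size):
                z = Tensor((latents[i:i + batch_size]
                            * self.latent_scale).astype(nn.DTYPE))
                out.append(np.clip(self.net.decoder(z).data, 0.0, 1.0))
        return np.transpose(np.concatenate(out), (0, 2, 3, 1))

    @property
    def compression_factor(self) -> float:
        c = self.net.cfg.latent_channels
        return 3 * 16 / c                       # (3*S*S) / (c*(S/4)^2)


def train_latent_autoencoder(images: np.ndarray,
                             config: AutoencoderConfig | None = None
                             ) -> LatentAutoencoder:
    """Fit the codec on (N, S, S, 3) images in [0,1]; deterministic by seed.

    Raises if the held-out reconstruction error stays above the configured
    bound (divergence guard), with the loss history attached.
    """
    cfg = config or AutoencoderConfig()
    if len(images) < 100:
        raise ValueError("need at least 100 images to fit the codec")
    rng = np.random.default_rng(cfg.seed)
    net = AutoencoderNet(cfg, rng).seed_rng(cfg.seed + 1)
    x_all = np.transpose(images, (0, 3, 1, 2)).astype(nn.DTYPE)
    order = rng.permutation(len(x_all))
    n_hold = max(1, int(cfg.holdout_frac * len(x_all)))
    hold, train = order[:n_hold], order[n_hold:]
    opt = nn.AdamW(net.parameters(), lr=cfg.lr, weight_decay=1e-5)
    history = []
    for epoch in range(cfg.epochs):
        net.train()
        perm = rng.permutation(train)
        losses = []
        for i in range(0, len(perm), cfg.batch_size):
            xb = Tensor(x_all[perm[i:i + cfg.batch_size]])
            if cfg.vq:
                recon, _, aux = net(xb, return_latent=True)
                loss = ((recon - xb) ** 2).mean() + aux
            else:
                recon = net(xb)
                loss = ((recon - xb) ** 2).mean()
            net.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    net.eval()
    with nn.no_grad():
        recon = net(Tensor(x_all[hold]))
        hold_mse = float(((recon.data - x_all[hold]) ** 2).mean())
    if hold_mse > cfg.max_holdout_mse:
        err = RuntimeError(
            f"autoencoder failed to converge: held-out MSE {hold_mse:.4f} "
            f"> bound {cfg.max_holdout_mse}")
        err.history = history                     # type: ignore[attr-defined]
        raise err
    ae = LatentAutoencoder(net=net, history=history)
    with nn.no_grad():
        z = net.encoder(Tensor(x_all[hold]))
        if cfg.vq:
            z, _, _ = net.quantize(z)
    ae.latent_scale = float(z.data.std()) or 1.0
    return ae
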