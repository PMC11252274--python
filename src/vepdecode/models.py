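"""Compact CNN classifier (EEGNet) and its 512-d embedding variant (EEGNet+).

EEGNet stacks a temporal convolution (learning frequency-selective filters),
a depthwise spatial convolution across all electrodes (per-filter spatial
patterns), and a separable convolution (depthwise temporal + pointwise mixing)
before a linear classifier.  The best configuration used here — 64 temporal
filters, depth multiplier 2, max pooling, dropout 0.25 — totals 62,612
trainable parameters for 8 channels x 500 samples x 20 classes.

EEGNet+ shares the backbone but replaces the classifier head with two linear
layers; the first (512 units) acts as the embedding read out by
:func:`extract_embedding` and used to condition the reconstruction model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor

EMBED_DIM = 512


@dataclass
class EEGNetConfig:
    """Architecture hyperparameters; defaults are the best configuration."""

    f1_temporal_filters: int = 64
    depth_multiplier: int = 2
    temporal_kernel_len: int = 64
    pool_mode: str = "max"              # "max" or "mean"
    pool_sizes: tuple[int, int] = (4, 8)
    dropout_p: float = 0.25
    n_channels: int = 8
    n_samples: int = 500
    n_classes: int = 20

    @property
    def f2(self) -> int:
        return self.f1_temporal_filters * self.depth_multiplier

    @property
    def n_features(self) -> int:
        """Flattened feature count entering the head."""
        p1, p2 = self.pool_sizes
        return self.f2 * (self.n_samples // p1 // p2)

    def validate(self):
        if self.pool_mode not in ("max", "mean"):
            raise ValueError(f"pool_mode must be 'max' or 'mean', got {self.pool_mode!r}")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must lie in [0, 1)")
        p1, p2 = self.pool_sizes
        if self.n_samples // p1 // p2 < 1:
            raise ValueError("pool sizes reduce the time axis below one sample")
        for name in ("f1_temporal_filters", "depth_multiplier",
                     "temporal_kernel_len", "n_channels", "n_samples", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        return self


class _Backbone(nn.Module):
    """Shared convolutional trunk of EEGNet and EEGNet+."""

    def __init__(self, cfg: EEGNetConfig, rng: np.random.Generator):
        super().__init__()
        f1, f2 = cfg.f1_temporal_filters, cfg.f2
        pool = nn.MaxPool2d if cfg.pool_mode == "max" else nn.AvgPool2d
        self.conv_temporal = nn.Conv2d(1, f1, (1, cfg.temporal_kernel_len), rng,
                                       padding="same", bias=False)
        self.bn_temporal = nn.BatchNorm2d(f1)
        self.conv_spatial = nn.Conv2d(f1, f2, (cfg.n_channels, 1), rng,
                                      groups=f1, bias=False)
        self.bn_spatial = nn.BatchNorm2d(f2)
        self.act1 = nn.ELU()
        self.pool1 = pool((1, cfg.pool_sizes[0]))
        self.drop1 = nn.Dropout(cfg.dropout_p)
        self.conv_sep_depth = nn.Conv2d(f2, f2, (1, 16), rng, padding="same",
                                        groups=f2, bias=False)
        self.conv_sep_point = nn.Conv2d(f2, f2, (1, 1), rng, bias=False)
        self.bn_sep = nn.BatchNorm2d(f2)
        self.act2 = nn.ELU()
        self.pool2 = pool((1, cfg.pool_sizes[1]))
        self.drop2 = nn.Dropout(cfg.dropout_p)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn_temporal(self.conv_temporal(x))
        x = self.act1(self.bn_spatial(self.conv_spatial(x)))
        x = self.drop1(self.pool1(x))
        x = self.act2(self.bn_sep(self.conv_sep_point(self.conv_sep_depth(x))))
        x = self.drop2(self.pool2(x))
        return x.reshape(x.shape[0], -1)


class EEGNet(nn.Module):
    def __init__(self, cfg: EEGNetConfig, rng: np.random.Generator):
        super().__init__()
        self.backbone = _Backbone(cfg, rng)
        self.classifier = nn.Linear(cfg.n_features, cfg.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.classifier(self.backbone(x))


class EEGNetPlus(nn.Module):
    def __init__(self, cfg: EEGNetConfig, rng: np.random.Generator,
                 embed_dim: int = EMBED_DIM):
        super().__init__()
        self.backbone = _Backbone(cfg, rng)
        self.embed = nn.Linear(cfg.n_features, embed_dim, rng)
        self.classifier = nn.Linear(embed_dim, cfg.n_classes, rng)

    def forward(self, x: Tensor, encoder_mode: bool = False) -> Tensor:
        y = self.embed(self.backbone(x))
        return y if encoder_mode else self.classifier(y)


@dataclass
class ModelHandle:
    """A built network plus its configuration and per-layer parameter inventory."""

    network: nn.Module
    config: EEGNetConfig
    kind: str                                    # "eegnet" | "eegnet_plus"
    embed_dim: int | None = None
    inventory: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.inventory:
            self.inventory = self.network.parameter_inventory()

    @property
    def n_parameters(self) -> int:
        total = self.network.n_parameters()
        assert total == sum(self.inventory.values())
        return total

    @property
    def is_encoder(self) -> bool:
        return self.kind == "eegnet_plus"

    def train(self):
        self.network.train()
        return self

    def eval(self):
        self.network.eval()
        return self

    def _as_input(self, epochs_data: np.ndarray) -> Tensor:
        x = np.asarray(epochs_data, dtype=nn.DTYPE)
        if x.ndim == 3:
            x = x[:, None, :, :]
        return Tensor(x)

    def logits(self, epochs_data: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Eval-mode class logits, computed without building a graph."""
        self.eval()
        out = []
        with nn.no_grad():
            for i in range(0, len(epochs_data), batch_size):
                out.append(self.network(self._as_input(epochs_data[i:i + batch_size])).data)
        return np.concatenate(out, axis=0)

    def predict(self, epochs_data: np.ndarray) -> np.ndarray:
        return self.logits(epochs_data).argmax(axis=1)


def build_eegnet(config: EEGNetConfig | None = None, seed: int = 0) -> ModelHandle:
    cfg = (config or EEGNetConfig()).validate()
    net = EEGNet(cfg, np.random.default_rng(seed)).seed_rng(seed + 1)
    return ModelHandle(net, cfg, "eegnet")


def build_eegnet_plus(config: EEGNetConfig | None = None,
                      embed_dim: int = EMBED_DIM, seed: int = 0) -> ModelHandle:
    if embed_dim <= 0:
        raise ValueError("embed_dim must be positive")
    cfg = (config or EEGNetConfig()).validate()
    net = EEGNetPlus(cfg, np.random.default_rng(seed), embed_dim).seed_rng(seed + 1)
    return ModelHandle(net, cfg, "eegnet_plus", embed_dim=embed_dim)


def extract_embedding(handle: ModelHandle, epochs, batch_size: int = 256) -> np.ndarray:
    """Embeddings (n_retained, 512) for every retained epoch, eval mode."""
    if not handle.is_encoder:
        raise ValueError("extract_embedding requires an EEGNet+ handle")
    data = epochs.retained_data() if hasattr(epochs, "retained_data") else np.asarray(epochs)
    handle.eval()
    out = []
    with nn.no_grad():
        for i in range(0, len(data), batch_size):
            x = handle._as_input(data[i:i + batch_size])
            out.append(handle.network(x, encoder_mode=True).data)
    return np.concatenate(out, axis=0)


# -- persistence ---------------------------------------------------------------

def save_checkpoint(handle: ModelHandle, path: str | Path):
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {"kind": handle.kind, "embed_dim": handle.embed_dim,
            "config": asdict(handle.config)}
    (path / "config.json").write_text(json.dumps(meta, indent=2))
    np.savez(path / "weights.npz", **handle.network.state_dict())
    pd.DataFrame(sorted(handle.inventory.items()),
                 columns=["layer", "count"]).to_csv(path / "inventory.csv", index=False)


def load_checkpoint(path: str | Path) -> ModelHandle:
    path = Path(path)
    meta = json.loads((path / "config.json").read_text())
    cfg_d = meta["config"]
    cfg_d["pool_sizes"] = tuple(cfg_d["pool_sizes"])
    cfg = EEGNetConfig(**cfg_d)
    if meta["kind"] == "eegnet":
        handle = build_eegnet(cfg)
    else:
        handle = build_eegnet_plus(cfg, embed_dim=meta["embed_dim"])
    with np.load(path / "weights.npz") as z:
        handle.network.load_state_dict(dict(z))
    return handle
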