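"""Reconstruction evaluation: surrogate image classifier and the n-way
top-1 protocol (with best-of-5 / mean-of-5 aggregation)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .. import nn
from ..nn import Tensor, cross_entropy_logits


class SurrogateClassifierNet(nn.Module):
    """Small CNN scoring images into the stimulus classes (the stand-in
    metric classifier used by the n-way protocol)."""

    def __init__(self, n_classes: int, side_px: int, rng):
        super().__init__()
        self.c1 = nn.Conv2d(3, 16, 3, rng, stride=2, padding="same")
        self.c2 = nn.Conv2d(16, 32, 3, rng, stride=2, padding="same")
        self.pool = nn.AvgPool2d((2, 2))
        feat = 32 * (side_px // 8) ** 2
        self.fc = nn.Linear(feat, n_classes, rng)

    def forward(self, x):
        h = self.c2(self.c1(x).silu()).silu()
        h = self.pool(h)
        return self.fc(h.reshape(h.shape[0], -1))


@dataclass
class SurrogateClassifier:
    net: SurrogateClassifierNet
    n_classes: int

    def scores(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class scores (softmax probabilities) for (N, S, S, 3) images."""
        self.net.eval()
        out = []
        with nn.no_grad():
            for i in range(0, len(images), batch_size):
                x = Tensor(np.transpose(images[i:i + batch_size], (0, 3, 1, 2))
                           .astype(nn.DTYPE))
                logits = self.net(x).data
                z = logits - logits.max(axis=1, keepdims=True)
                p = np.exp(z)
                out.append(p / p.sum(axis=1, keepdims=True))
        return np.concatenate(out)

    def accuracy(self, images: np.ndarray, labels: np.ndarray) -> float:
        return float((self.scores(images).argmax(axis=1) == labels).mean())


def train_surrogate(images: np.ndarray, labels: np.ndarray, n_classes: int,
                    epochs: int = 30, batch_size: int = 64, lr: float = 3e-3,
                    seed: int = 0) -> SurrogateClassifier:
    rng = np.random.default_rng(seed)
    net = SurrogateClassifierNet(n_classes, images.shape[1], rng) \
        .seed_rng(seed + 1)
    x_all = np.transpose(images, (0, 3, 1, 2)).astype(nn.DTYPE)
    y_all = np.asarray(labels, dtype=np.int64)
    opt = nn.AdamW(net.parameters(), lr=lr, weight_decay=1e-4)
    for _ in range(epochs):
        net.train()
        order = rng.permutation(len(x_all))
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            loss = cross_entropy_logits(net(Tensor(x_all[idx])), y_all[idx])
            net.zero_grad()
            loss.backward()
            opt.step()
    return SurrogateClassifier(net=net, n_classes=n_classes)


def n_way_top1_from_scores(scores: np.ndarray, true_labels: np.ndarray,
                           n: int, trials: int, seed: int) -> np.ndarray:
    """Per-image n-way top-1 accuracy from precomputed class scores.

    Each trial draws n-1 distractor classes uniformly without replacement;
    success iff the true class has the strictly highest score among the n.
    ``n = 1`` is trivially 1.0.
    """
    scores = np.asarray(scores)
    true_labels = np.asarray(true_labels)
    n_classes = scores.shape[1]
    if n < 1 or n > n_classes:
        raise ValueError(f"n must lie in 1..{n_classes}")
    if n == 1:
        return np.ones(len(scores))
    rng = np.random.default_rng(seed)
    out = np.empty(len(scores))
    for i, (s, lab) in enumerate(zip(scores, true_labels)):
        others = np.delete(np.arange(n_classes), lab)
        # vectorised sampling without replacement: random keys, take n-1 smallest
        keys = rng.random((trials, len(others)))
        distract = others[np.argpartition(keys, n - 2, axis=1)[:, :n - 1]]
        out[i] = float(np.mean(s[lab] > s[distract].max(axis=1)))
    return out


def n_way_top1(images: np.ndarray, true_labels: np.ndarray,
               classifier: SurrogateClassifier, n: int,
               trials: int = 1000, seed: int = 0) -> float:
    """Mean n-way top-1 accuracy of generated images under the surrogate."""
    per_image = n_way_top1_from_scores(classifier.scores(images), true_labels,
                                       n, trials, seed)
    return float(per_image.mean())


@dataclass
class ReconstructionReport:
    """Per-image generated samples and their n-way top-1 accuracies."""

    n_way: int
    trials: int
    per_image_sample_acc: np.ndarray      # (n_images, n_samples)
    labels: np.ndarray
    sample_seeds: list = field(default_factory=list)

    def __post_init__(self):
        acc = np.asarray(self.per_image_sample_acc)
        assert np.all((acc >= 0) & (acc <= 1))

    @property
    def best_of_samples(self) -> float:
        return float(self.per_image_sample_acc.max(axis=1).mean())

    @property
    def mean_of_samples(self) -> float:
        return float(self.per_image_sample_acc.mean())

    @property
    def per_image_best(self) -> np.ndarray:
        return self.per_image_sample_acc.max(axis=1)

    def to_json(self, path: str | Path):
        Path(path).write_text(json.dumps({
            "n_way": self.n_way,
            "trials": self.trials,
            "best_of_samples_pct": 100 * self.best_of_samples,
            "mean_of_samples_pct": 100 * self.mean_of_samples,
            "per_image_best_pct": (100 * self.per_image_best).tolist(),
            "sample_seeds": self.sample_seeds,
        }, indent=2))


def evaluate_reconstructions(samples: np.ndarray, labels: np.ndarray,
                             classifier: SurrogateClassifier, n: int,
                             trials: int = 1000, seed: int = 0,
                             sample_seeds: list | None = None
                             ) -> ReconstructionReport:
    """samples: (n_images, n_samples, S, S, 3) generated images."""
    n_img, n_samp = samples.shape[:2]
    acc = np.empty((n_img, n_samp))
    for j in range(n_samp):
        acc[:, j] = n_way_top1_from_scores(
            classifier.scores(samples[:, j]), labels, n, trials, seed + j)
    return ReconstructionReport(n_way=n, trials=trials,
                                per_image_sample_acc=acc, labels=np.asarray(labels),
                                sample_seeds=sample_seeds or [])
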