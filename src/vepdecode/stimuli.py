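"""Parametric stimulus images standing in for natural image categories.

Each class is a coloured geometric figure (disc, ring, cross, square,
diamond — cycled, with a class-specific hue) on a class-specific gray
background.  Within a class, position, size and hue jitter create variation
while the background level keeps the class's mean luminance coherent — the
low-level within-class coherence (silhouette + luminance) that makes the
categories separable for a small surrogate image classifier.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .sim import SessionSpec

SHAPES = ("disc", "ring", "cross", "square", "diamond")


@dataclass
class StimulusImageSet:
    """Images in [0, 1], shape (n_classes, images_per_class, side, side, 3)."""

    images: np.ndarray
    class_hues: np.ndarray
    class_shapes: list[str]

    @property
    def n_classes(self) -> int:
        return self.images.shape[0]

    @property
    def images_per_class(self) -> int:
        return self.images.shape[1]

    @property
    def side_px(self) -> int:
        return self.images.shape[2]

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_total, side, side, 3) images and their integer labels."""
        n_c, n_i = self.images.shape[:2]
        labels = np.repeat(np.arange(n_c), n_i)
        return self.images.reshape(n_c * n_i, *self.images.shape[2:]), labels

    def luminance(self) -> np.ndarray:
        """Mean luminance (Rec. 601) per image, shape (n_classes, images_per_class)."""
        w = np.array([0.299, 0.587, 0.114])
        return np.tensordot(self.images, w, axes=([-1], [0])).mean(axis=(-1, -2))

    def save_pngs(self, out_dir: str | Path) -> pd.DataFrame:
        """Write one PNG per image plus a manifest CSV (path, class_id, image_id)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for c in range(self.n_classes):
            for i in range(self.images_per_class):
                name = f"class{c:02d}_img{i:02d}.png"
                arr = (np.clip(self.images[c, i], 0, 1) * 255).astype(np.uint8)
                Image.fromarray(arr).save(out_dir / name)
                rows.append({"path": name, "class_id": c, "image_id": i})
        manifest = pd.DataFrame(rows)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        return manifest


def _shape_mask(kind: str, side: int, cx: float, cy: float, r: float) -> np.ndarray:
    y, x = np.mgrid[0:side, 0:side].astype(float)
    dx, dy = x - cx, y - cy
    rho = np.hypot(dx, dy)
    if kind == "disc":
        return rho <= r
    if kind == "ring":
        return (rho <= r) & (rho >= 0.55 * r)
    if kind == "cross":
        return ((np.abs(dx) <= 0.3 * r) | (np.abs(dy) <= 0.3 * r)) \
            & (np.abs(dx) <= r) & (np.abs(dy) <= r)
    if kind == "square":
        return (np.abs(dx) <= r * 0.85) & (np.abs(dy) <= r * 0.85)
    if kind == "diamond":
        return (np.abs(dx) + np.abs(dy)) <= 1.2 * r
    raise ValueError(f"unknown shape {kind!r}")


def generate_stimulus_images(spec: SessionSpec, side_px: int = 64,
                             seed: int = 0) -> StimulusImageSet:
    """Deterministically generate ``images_per_class`` images for every class."""
    if side_px < 16:
        raise ValueError("side_px must be at least 16")
    rng = np.random.default_rng(seed)
    n_c, n_i = spec.n_classes, spec.images_per_class

    hues = (np.arange(n_c) / n_c + rng.uniform(0, 1 / (2 * n_c), n_c)) % 1.0
    # distinct background grays keep between-class luminance spread large
    bg_levels = rng.permutation(np.linspace(0.25, 0.75, n_c))
    shapes = [SHAPES[c % len(SHAPES)] for c in range(n_c)]

    images = np.empty((n_c, n_i, side_px, side_px, 3), dtype=np.float32)
    for c in range(n_c):
        base_rgb = np.array(colorsys.hsv_to_rgb(hues[c], 0.85, 0.9))
        for i in range(n_i):
            bg = bg_levels[c] + rng.uniform(-0.02, 0.02)
            img = np.full((side_px, side_px, 3), bg, dtype=np.float32)
            img += rng.normal(0, 0.01, img.shape).astype(np.float32)
            cx = side_px / 2 + rng.uniform(-0.12, 0.12) * side_px
            cy = side_px / 2 + rng.uniform(-0.12, 0.12) * side_px
            r = side_px * rng.uniform(0.22, 0.3)
            mask = _shape_mask(shapes[c], side_px, cx, cy, r)
            jitter_rgb = np.clip(base_rgb + rng.uniform(-0.05, 0.05, 3), 0, 1)
            img[mask] = jitter_rgb.astype(np.float32)
            images[c, i] = np.clip(img, 0.0, 1.0)
    return StimulusImageSet(images=images, class_hues=hues, class_shapes=shapes)
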