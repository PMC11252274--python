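"""Inter-trial (gray-screen) null control for the reconstruction pathway.

The 1 s inter-trial intervals carry no stimulus-evoked signal.  Feeding them
through the same encoder -> sampler -> metric chain measures how much of the
reconstruction accuracy is driven by the model rather than by the EEG input:
a stimulus-dependent system scores near chance here.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from ..models import ModelHandle, extract_embedding
from ..sim import RawRecording
from .metrics import SurrogateClassifier, evaluate_reconstructions, ReconstructionReport
from .sampler import sample_plms
from .schedule import DiffusionSchedule
from .unet import ConditionedUNet


def extract_intertrial_windows(rec: RawRecording, max_windows: int | None = None
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Gray-screen segments (n, 8, isi_samples) plus the class shown just
    before each segment (the label used for the control metric)."""
    spec = rec.events.spec
    isi = spec.isi_samples
    win = spec.stim_samples
    segs, labels = [], []
    n = rec.signal.shape[1]
    for onset, cls in zip(rec.events.onsets, rec.events.class_ids):
        a = int(onset) + win
        if a + isi <= n:
            seg = rec.signal[:, a:a + isi]
            if np.all(np.isfinite(seg)):
                segs.append(seg)
                labels.append(int(cls))
        if max_windows is not None and len(segs) >= max_windows:
            break
    if not segs:
        raise ValueError("recording contains no usable inter-trial windows")
    return np.stack(segs), np.asarray(labels)


def upsample_windows(segments: np.ndarray, target_len: int,
                     method: str = "linear") -> np.ndarray:
    """Stretch (n, 8, m) segments to ``target_len`` samples per channel."""
    n, n_ch, m = segments.shape
    if method == "linear":
        xi = np.linspace(0, m - 1, target_len)
        x0 = np.arange(m)
        out = np.empty((n, n_ch, target_len), dtype=segments.dtype)
        for i in range(n):
            for c in range(n_ch):
                out[i, c] = np.interp(xi, x0, segments[i, c])
        return out
    if method == "fourier":
        return sps.resample(segments, target_len, axis=2)
    raise ValueError(f"unknown upsampling method {method!r}")


def normalize_channelwise(segments: np.ndarray) -> np.ndarray:
    """z-score each channel over all null segments (mirrors the session-level
    channel-wise normalisation of real trials)."""
    mean = segments.mean(axis=(0, 2), keepdims=True)
    sd = segments.std(axis=(0, 2), keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant channel in null segments")
    return (segments - mean) / sd


def null_control(rec: RawRecording, encoder: ModelHandle,
                 unet: ConditionedUNet, schedule: DiffusionSchedule,
                 decoder, classifier: SurrogateClassifier,
                 n_way: int, steps: int = 25, n_samples: int = 5,
                 trials: int = 1000, seed: int = 0,
                 max_windows: int | None = None,
                 upsample_method: str = "linear",
                 latent_hw: int = 16,
                 embed_transform=None,
                 clip_x0: float | None = None) -> ReconstructionReport:
    """Run the full reconstruction chain on inter-trial EEG segments."""
    segs, labels = extract_intertrial_windows(rec, max_windows)
    target = rec.events.spec.stim_samples
    up = upsample_windows(segs, target, method=upsample_method)
    up = normalize_channelwise(up)
    emb = extract_embedding(encoder, up)
    if embed_transform is not None:
        emb = embed_transform(emb)
    latent_shape = (unet.cfg.latent_channels, latent_hw, latent_hw)
    all_samples = []
    seeds = []
    for s in range(n_samples):
        imgs = sample_plms(unet, schedule, emb, latent_shape, steps,
                           seed=seed + 1000 + s, decoder=decoder,
                           clip_x0=clip_x0)
        all_samples.append(imgs)
        seeds.append(seed + 1000 + s)
    samples = np.stack(all_samples, axis=1)      # (n_img, n_samples, S, S, 3)
    return evaluate_reconstructions(samples, labels, classifier, n_way,
                                    trials=trials, seed=seed, sample_seeds=seeds)
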