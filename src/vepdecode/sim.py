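"""Synthetic VEP session generator.

Emulates an 8-channel occipito-parietal EEG recording of a rapid serial
image-presentation experiment: each stimulus evokes a class-specific
N1–P2 onset complex (negative deflection near 100 ms, positive near 200 ms)
on top of 1/f background noise, mains interference and white sensor noise.
Stimuli are shown for 2 s separated by a 1 s gray screen; the gray-screen
intervals contain noise only, which is what makes them usable as a
stimulus-free null control downstream.

Class identity is carried by per-class N1/P2 latencies and amplitudes and by
a per-class spatial gain pattern across the electrodes; a single ``snr`` knob
rescales all evoked amplitudes relative to the background-noise standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_CHANNELS = ("PO8", "O2", "O1", "PO7", "PO3", "POZ", "PO4", "Pz")


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered 10–20 electrode labels of the 8-channel montage."""

    names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self):
        if len(self.names) != 8 or len(set(self.names)) != 8:
            raise ValueError("layout requires exactly 8 unique channel labels")

    @property
    def n_channels(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class SessionSpec:
    """Timing and size of one recording session."""

    n_classes: int = 20
    images_per_class: int = 30
    stim_dur_s: float = 2.0
    isi_s: float = 1.0
    fs_hz: float = 250.0
    lead_in_s: float = 1.0      # quiet head-room before the first stimulus

    def __post_init__(self):
        for name in ("n_classes", "images_per_class", "stim_dur_s", "isi_s", "fs_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.stim_dur_s * self.fs_hz - round(self.stim_dur_s * self.fs_hz)) > 1e-9:
            raise ValueError("stim_dur_s * fs_hz must be an integer number of samples")
        if abs(self.trial_spacing_s * self.fs_hz
               - round(self.trial_spacing_s * self.fs_hz)) > 1e-9:
            raise ValueError("(stim_dur_s + isi_s) * fs_hz must be an integer")

    @property
    def n_trials(self) -> int:
        return self.n_classes * self.images_per_class

    @property
    def stim_samples(self) -> int:
        return int(round(self.stim_dur_s * self.fs_hz))

    @property
    def isi_samples(self) -> int:
        return int(round(self.isi_s * self.fs_hz))

    @property
    def trial_spacing_s(self) -> float:
        return self.stim_dur_s + self.isi_s

    @property
    def trial_spacing_samples(self) -> int:
        return self.stim_samples + self.isi_samples


@dataclass(frozen=True)
class EventList:
    """Stimulus onsets: (onset_sample, class_id, image_id), 0-based samples."""

    onsets: np.ndarray          # int64 (n,)
    class_ids: np.ndarray       # int64 (n,)
    image_ids: np.ndarray       # int64 (n,)
    spec: SessionSpec

    def __post_init__(self):
        o = np.asarray(self.onsets)
        if len(o) > 1:
            d = np.diff(o)
            if not np.all(d > 0):
                raise ValueError("onsets must be strictly increasing")
            if not np.all(d == self.spec.trial_spacing_samples):
                raise ValueError("inter-onset spacing must equal (stim+isi)*fs")

    def __len__(self):
        return len(self.onsets)

    @property
    def duration_s(self) -> float:
        """Span of the stimulus sequence: first onset to end of last ISI."""
        return len(self) * self.spec.trial_spacing_s


@dataclass
class VEPModel:
    """Per-class evoked-response template parameters plus noise model.

    Amplitudes are in µV; each class contributes a negative N1 lobe and a
    positive P2 lobe (Gaussian-windowed), scaled per channel by its spatial
    signature.  ``shape_jitter_sd`` jitters single-trial latencies (ms);
    ``trial_amp_jitter_sd`` multiplicatively jitters single-trial amplitude.
    """

    n1_latency_ms: np.ndarray       # (n_classes,)
    n1_amp_uv: np.ndarray           # negative
    p2_latency_ms: np.ndarray
    p2_amp_uv: np.ndarray           # positive
    spatial_signature: np.ndarray   # (n_classes, 8) channel gains
    shape_jitter_sd: float = 5.0
    n1_width_ms: float = 22.0
    p2_width_ms: float = 38.0
    # noise model
    pink_exponent: float = 1.0
    pink_sd_uv: float = 4.0
    white_sd_uv: float = 2.0
    line_amp_uv: float = 1.0
    line_freq_hz: float = 60.0
    trial_amp_jitter_sd: float = 0.1

    def __post_init__(self):
        for arr in (self.n1_latency_ms, self.p2_latency_ms):
            if np.any(np.asarray(arr) <= 0):
                raise ValueError("latencies must be positive")
        if not np.all(np.isfinite(self.spatial_signature)):
            raise ValueError("spatial signatures must be finite")
        for name in ("pink_sd_uv", "white_sd_uv", "line_amp_uv",
                     "trial_amp_jitter_sd", "shape_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_classes(self) -> int:
        return len(self.n1_latency_ms)

    @property
    def noise_sd_uv(self) -> float:
        """Total background SD (pink + white + line, independent sources)."""
        return float(np.sqrt(self.pink_sd_uv ** 2 + self.white_sd_uv ** 2
                             + self.line_amp_uv ** 2 / 2))

    @classmethod
    def default(cls, n_classes: int = 20, snr: float = 2.0,
                seed: int = 7, n_channels: int = 8) -> "VEPModel":
        """Draw a class-discriminable template set at the requested SNR.

        ``snr`` is the ratio of the median absolute P2 peak amplitude to the
        background-noise SD; ``snr=0`` yields flat (zero) templates, leaving
        pure noise.
        """
        rng = np.random.default_rng(seed)
        n1_lat = rng.uniform(85.0, 135.0, n_classes)
        p2_lat = n1_lat + rng.uniform(70.0, 110.0, n_classes)
        n1_amp = -rng.uniform(0.6, 1.4, n_classes)
        p2_amp = rng.uniform(0.6, 1.4, n_classes)
        sig = rng.uniform(0.3, 1.2, (n_classes, n_channels))
        model = cls(n1_latency_ms=n1_lat, n1_amp_uv=n1_amp,
                    p2_latency_ms=p2_lat, p2_amp_uv=p2_amp,
                    spatial_signature=sig)
        scale = snr * model.noise_sd_uv / max(np.median(np.abs(p2_amp)), 1e-12)
        model.n1_amp_uv = n1_amp * scale
        model.p2_amp_uv = p2_amp * scale
        return model

    def noiseless(self) -> "VEPModel":
        """Copy with all noise and jitter switched off (templates only)."""
        return replace(self, pink_sd_uv=0.0, white_sd_uv=0.0, line_amp_uv=0.0,
                       shape_jitter_sd=0.0, trial_amp_jitter_sd=0.0)

    def class_template(self, class_id: int, fs_hz: float, n_samples: int,
                       lat_shift_ms: float = 0.0, amp_scale: float = 1.0
                       ) -> np.ndarray:
        """Single-channel template (before spatial scaling), length n_samples."""
        t_ms = np.arange(n_samples) / fs_hz * 1000.0
        n1 = self.n1_amp_uv[class_id] * np.exp(
            -0.5 * ((t_ms - self.n1_latency_ms[class_id] - lat_shift_ms)
                    / self.n1_width_ms) ** 2)
        p2 = self.p2_amp_uv[class_id] * np.exp(
            -0.5 * ((t_ms - self.p2_latency_ms[class_id] - lat_shift_ms)
                    / self.p2_width_ms) ** 2)
        return amp_scale * (n1 + p2)


@dataclass
class RawRecording:
    """Continuous multichannel signal (µV) with its event markers."""

    signal: np.ndarray              # (8, N) float
    fs_hz: float
    layout: ChannelLayout
    events: EventList
    session_id: str = "session-000"

    def __post_init__(self):
        if self.signal.shape[0] != self.layout.n_channels:
            raise ValueError("signal must have one row per channel")
        need = int(self.events.onsets[-1]) + self.events.spec.stim_samples
        if self.signal.shape[1] < need:
            raise ValueError("recording shorter than last stimulus window")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def copy(self) -> "RawRecording":
        return replace(self, signal=self.signal.copy())


def make_session_events(spec: SessionSpec, seed: int) -> EventList:
    """Random presentation order of the full stimulus set, evenly spaced."""
    rng = np.random.default_rng(seed)
    class_ids = np.repeat(np.arange(spec.n_classes), spec.images_per_class)
    image_ids = np.tile(np.arange(spec.images_per_class), spec.n_classes)
    order = rng.permutation(spec.n_trials)
    lead = int(round(spec.lead_in_s * spec.fs_hz))
    onsets = lead + np.arange(spec.n_trials, dtype=np.int64) \
        * spec.trial_spacing_samples
    return EventList(onsets=onsets, class_ids=class_ids[order],
                     image_ids=image_ids[order], spec=spec)


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int,
                exponent: float, sd: float) -> np.ndarray:
    """1/f^exponent noise via spectral shaping of white noise, unit-SD scaled."""
    if sd == 0:
        return np.zeros((n_ch, n))
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    shaped = np.fft.irfft(spec * shaping, n=n, axis=1)
    shaped /= shaped.std(axis=1, keepdims=True)
    return sd * shaped


def synthesize_recording(events: EventList, model: VEPModel, seed: int,
                         layout: ChannelLayout | None = None,
                         session_id: str = "session-000") -> RawRecording:
    """Render a continuous recording: evoked templates in stimulus windows,
    background noise everywhere."""
    spec = events.spec
    layout = layout or ChannelLayout()
    if model.n_classes < spec.n_classes:
        raise ValueError("VEP model has fewer classes than the session spec")
    rng = np.random.default_rng(seed)
    n_ch = layout.n_channels
    n = int(events.onsets[-1]) + spec.stim_samples + spec.isi_samples

    sig = _pink_noise(rng, n_ch, n, model.pink_exponent, model.pink_sd_uv)
    if model.white_sd_uv > 0:
        sig += model.white_sd_uv * rng.standard_normal((n_ch, n))
    if model.line_amp_uv > 0:
        t = np.arange(n) / spec.fs_hz
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        sig += model.line_amp_uv * np.sin(
            2 * np.pi * model.line_freq_hz * t[None, :] + phases[:, None])

    win = spec.stim_samples
    for onset, cls in zip(events.onsets, events.class_ids):
        shift = rng.normal(0.0, model.shape_jitter_sd) if model.shape_jitter_sd else 0.0
        scale = 1.0 + (rng.normal(0.0, model.trial_amp_jitter_sd)
                       if model.trial_amp_jitter_sd else 0.0)
        template = model.class_template(int(cls), spec.fs_hz, win, shift, scale)
        sig[:, onset:onset + win] += \
            model.spatial_signature[int(cls), :n_ch, None] * template[None, :]
    return RawRecording(signal=sig, fs_hz=spec.fs_hz, layout=layout,
                        events=events, session_id=session_id)


#: artifact kinds understood by :func:`inject_artifacts`
ARTIFACT_KINDS = ("nan", "flat", "clone_channel", "burst")


def inject_artifacts(rec: RawRecording,
                     artifacts: list[tuple[int, str]],
                     seed: int = 0) -> RawRecording:
    """Corrupt the named trials; all other samples are untouched.

    kinds: ``nan`` (NaN samples in one channel), ``flat`` (one channel held
    constant), ``clone_channel`` (one channel copied onto another, emulating a
    bridged electrode), ``burst`` (high-amplitude broadband noise burst).
    """
    out = rec.copy()
    rng = np.random.default_rng(seed)
    spec = rec.events.spec
    win = spec.stim_samples
    n_trials = len(rec.events)
    for trial_idx, kind in artifacts:
        if not 0 <= trial_idx < n_trials:
            raise IndexError(f"trial index {trial_idx} out of range (0..{n_trials - 1})")
        if kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {kind!r}")
        a = int(rec.events.onsets[trial_idx])
        b = a + win
        ch = int(rng.integers(rec.layout.n_channels))
        if kind == "nan":
            k = int(rng.integers(win // 2))
            out.signal[ch, a + k:a + k + 5] = np.nan
        elif kind == "flat":
            out.signal[ch, a:b] = out.signal[ch, a]
        elif kind == "clone_channel":
            other = (ch + 1 + int(rng.integers(rec.layout.n_channels - 1))) \
                % rec.layout.n_channels
            out.signal[other, a:b] = out.signal[ch, a:b]
        elif kind == "burst":
            out.signal[:, a:b] += 200.0 * rng.standard_normal((rec.layout.n_channels, win))
    return out
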