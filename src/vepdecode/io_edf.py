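"""EDF (16-bit) session files and their tab-separated event sidecars.

The writer emits plain EDF: 1-second data records, one int16 stream per
channel, physical units µV with a symmetric per-channel physical range.
Because EDF has no representation for missing samples, NaNs (used by the
artifact fixtures) are encoded as the reserved digital code -32768 and mapped
back to NaN by :func:`read_edf`; all regular samples use -32767..32767.
``mne.io.read_raw_edf`` reads these files directly (NaN sentinel samples
appear as the most negative physical value there).

The events sidecar has columns onset_sample, onset_s, duration_s, class_id,
image_id with 0-based sample indices and half-open stimulus windows.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .sim import ChannelLayout, EventList, RawRecording, SessionSpec

_NAN_SENTINEL = -32768


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: RawRecording, path: str | Path,
              events_path: str | Path | None = None) -> Path:
    """Write the recording as 16-bit EDF (and its events TSV when given)."""
    path = Path(path)
    fs = rec.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))                       # samples per 1-s record
    n_ch, n = rec.signal.shape
    n_rec = int(np.ceil(n / spr))
    sig = np.zeros((n_ch, n_rec * spr), dtype=float)
    sig[:, :n] = rec.signal

    finite = np.isfinite(sig)
    absmax = np.abs(np.where(finite, sig, 0.0)).max(axis=1)
    phys_max = np.maximum(absmax, 1e-3) * 1.0000001
    dig_max = 32767

    header = b"".join([
        _pad("0", 8),
        _pad(f"session {rec.session_id}", 80),
        _pad("synthetic VEP recording", 80),
        _pad("01.01.24", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (1 + n_ch)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(n_ch), 4),
    ])
    labels = b"".join(_pad(name, 16) for name in rec.layout.names)
    transducer = b"".join(_pad("AgAgCl electrode", 80) for _ in range(n_ch))
    phys_dim = b"".join(_pad("uV", 8) for _ in range(n_ch))
    p_min = b"".join(_pad(f"{-m:.6g}"[:8], 8) for m in phys_max)
    p_max = b"".join(_pad(f"{m:.6g}"[:8], 8) for m in phys_max)
    d_min = b"".join(_pad(str(-dig_max), 8) for _ in range(n_ch))
    d_max = b"".join(_pad(str(dig_max), 8) for _ in range(n_ch))
    prefilter = b"".join(_pad("none", 80) for _ in range(n_ch))
    n_samp = b"".join(_pad(str(spr), 8) for _ in range(n_ch))
    reserved = b"".join(_pad("", 32) for _ in range(n_ch))

    # use the *written* physical range for quantisation
    written_max = np.array([float(f"{m:.6g}"[:8]) for m in phys_max])
    scale = dig_max / written_max
    digital = np.where(
        np.isfinite(sig),
        np.clip(np.round(sig * scale[:, None]), -dig_max, dig_max),
        _NAN_SENTINEL,
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + phys_dim + p_min + p_max
                 + d_min + d_max + prefilter + n_samp + reserved)
        # records: per record, each channel's block sequentially
        fh.write(np.ascontiguousarray(
            digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)).tobytes())

    if events_path is not None:
        write_events_tsv(rec.events, events_path)
    return path


def write_events_tsv(events: EventList, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "onset_sample": events.onsets.astype(int),
        "onset_s": events.onsets / events.spec.fs_hz,
        "duration_s": events.spec.stim_dur_s,
        "class_id": events.class_ids.astype(int),
        "image_id": events.image_ids.astype(int),
    })
    df.to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path, spec: SessionSpec) -> EventList:
    df = pd.read_csv(path, sep="\t")
    return EventList(onsets=df["onset_sample"].to_numpy(np.int64),
                     class_ids=df["class_id"].to_numpy(np.int64),
                     image_ids=df["image_id"].to_numpy(np.int64),
                     spec=spec)


def read_edf(path: str | Path, events_path: str | Path,
             spec: SessionSpec, session_id: str | None = None) -> RawRecording:
    """Read a session written by :func:`write_edf` (NaN sentinel restored)."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_rec = int(head[236:244].decode().strip())
        n_ch = int(head[252:256].decode().strip())
        sig_head = fh.read(256 * n_ch)
        raw = np.frombuffer(fh.read(), dtype="<i2")

    def field(block: bytes, width: int, i: int) -> str:
        return block[i * width:(i + 1) * width].decode().strip()

    off = 0
    labels = [field(sig_head[off:off + 16 * n_ch], 16, i) for i in range(n_ch)]
    off += 16 * n_ch + 80 * n_ch + 8 * n_ch          # skip transducer, phys dim
    p_min = np.array([float(field(sig_head[off:off + 8 * n_ch], 8, i))
                      for i in range(n_ch)])
    off += 8 * n_ch
    p_max = np.array([float(field(sig_head[off:off + 8 * n_ch], 8, i))
                      for i in range(n_ch)])
    off += 8 * n_ch
    d_min = np.array([float(field(sig_head[off:off + 8 * n_ch], 8, i))
                      for i in range(n_ch)])
    off += 8 * n_ch
    d_max = np.array([float(field(sig_head[off:off + 8 * n_ch], 8, i))
                      for i in range(n_ch)])
    off += 8 * n_ch + 80 * n_ch
    spr = np.array([int(field(sig_head[off:off + 8 * n_ch], 8, i))
                    for i in range(n_ch)])
    if len(set(spr.tolist())) != 1:
        raise ValueError("mixed samples-per-record not supported")
    spr = int(spr[0])

    digital = raw.reshape(n_rec, n_ch, spr).transpose(1, 0, 2) \
                 .reshape(n_ch, n_rec * spr).astype(float)
    gain = (p_max - p_min) / (d_max - d_min)
    sig = (digital - d_min[:, None]) * gain[:, None] + p_min[:, None]
    sig[np.asarray(digital == _NAN_SENTINEL)] = np.nan

    events = read_events_tsv(events_path, spec)
    need = int(events.onsets[-1]) + spec.stim_samples
    if sig.shape[1] < need:
        raise ValueError("EDF shorter than required by the event list")
    return RawRecording(signal=sig, fs_hz=float(spec.fs_hz),
                        layout=ChannelLayout(tuple(labels)), events=events,
                        session_id=session_id or path.stem)
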