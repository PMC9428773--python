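"""WAV input/output, 16 kHz mono normalization, and fixed-length framing.

The detector consumes 0.195 s windows of 16 kHz mono audio (3120 samples).
This module reads arbitrary PCM/float WAV files, collapses them to mono,
resamples to the detector rate, and slices signals either into gapless
frames or into a sliding most-recent-window stream at a configurable tick
rate (default 30 Hz, the cadence at which the deployed detector polled its
ring buffer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

TARGET_RATE = 16_000
FRAME_SAMPLES = 3120
FRAME_SECONDS = FRAME_SAMPLES / TARGET_RATE  # 0.195 s
DEFAULT_TICK_HZ = 30.0

__all__ = [
    "AudioClip",
    "Frame",
    "TARGET_RATE",
    "FRAME_SAMPLES",
    "FRAME_SECONDS",
    "read_wav",
    "write_wav",
    "resample_to_16k",
    "frame_clip",
    "sliding_window",
]


@dataclass(frozen=True)
class AudioClip:
    """Mono audio with samples in [-1, 1] and an explicit sample rate."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioClip samples must be one-dimensional (mono)")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("AudioClip samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be a positive integer")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class Frame:
    """One 3120-sample (0.195 s) detector input window."""

    samples: np.ndarray
    index: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.size != FRAME_SAMPLES:
            raise ValueError(
                f"Frame must hold exactly {FRAME_SAMPLES} samples, got {samples.size}"
            )
        object.__setattr__(self, "samples", samples)

    @property
    def start_s(self) -> float:
        return self.index * FRAME_SECONDS


_PCM_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


def read_wav(path: str | Path) -> AudioClip:
    """Read a RIFF/WAV file into a mono [-1, 1] clip at its native rate.

    Stereo (or any multi-channel) audio is averaged across channels.
    Integer PCM is scaled by the full-scale value of its bit depth; float
    files are taken as already normalized. 24-bit PCM arrives from scipy
    as int32 with the low byte zero, so the int32 scale applies.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (ValueError, EOFError, FileNotFoundError) as exc:
        raise OSError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.atleast_1d(data)
    if data.dtype == np.uint8:  # 8-bit PCM is unsigned, midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioClip(samples=samples, sample_rate=int(rate))


def write_wav(path: str | Path, clip: AudioClip, bit_depth: int = 16) -> None:
    """Write a clip as PCM WAV (16-bit default, 32-bit float with bit_depth=32)."""
    if bit_depth == 16:
        scaled = np.clip(clip.samples, -1.0, 1.0)
        data = np.round(scaled * (2**15 - 1)).astype(np.int16)
    elif bit_depth == 32:
        data = clip.samples.astype(np.float32)
    else:
        raise ValueError("bit_depth must be 16 or 32")
    wavfile.write(Path(path), clip.sample_rate, data)


def resample_to_16k(clip: AudioClip) -> AudioClip:
    """Band-limited polyphase resampling to the 16 kHz detector rate.

    A clip already at 16 kHz is returned unchanged. Output length is
    round(n * 16000 / input_rate).
    """
    if clip.sample_rate == TARGET_RATE:
        return clip
    g = math.gcd(TARGET_RATE, clip.sample_rate)
    up, down = TARGET_RATE // g, clip.sample_rate // g
    resampled = resample_poly(clip.samples, up, down)
    # resample_poly yields ceil(n*up/down); trim/pad to the rounded length
    target_len = round(clip.samples.size * TARGET_RATE / clip.sample_rate)
    if resampled.size > target_len:
        resampled = resampled[:target_len]
    elif resampled.size < target_len:
        resampled = np.pad(resampled, (0, target_len - resampled.size))
    return AudioClip(samples=resampled, sample_rate=TARGET_RATE)


def _require_16k(clip: AudioClip) -> None:
    if clip.sample_rate != TARGET_RATE:
        raise ValueError(
            f"clip must be at {TARGET_RATE} Hz (got {clip.sample_rate}); "
            "call resample_to_16k first"
        )


def frame_clip(clip: AudioClip) -> list[Frame]:
    """Cut a 16 kHz clip into gapless non-overlapping 3120-sample frames.

    A trailing remainder shorter than one frame is dropped, never padded.
    """
    _require_16k(clip)
    n_frames = clip.samples.size // FRAME_SAMPLES
    return [
        Frame(samples=clip.samples[i * FRAME_SAMPLES : (i + 1) * FRAME_SAMPLES], index=i)
        for i in range(n_frames)
    ]


def sliding_window(
    clip: AudioClip, tick_hz: float = DEFAULT_TICK_HZ
) -> Iterator[tuple[float, Frame]]:
    """Stream (time, window) pairs: the most recent 0.195 s at each tick.

    Emulates a ring buffer polled ``tick_hz`` times per second. The first
    emission is at t = 0.195 s (the earliest full window); the last at the
    final tick not exceeding the clip duration. Windows overlap whenever
    the tick period is shorter than a frame.
    """
    _require_16k(clip)
    if tick_hz <= 0:
        raise ValueError("tick_hz must be positive")
    if clip.samples.size < FRAME_SAMPLES:
        return
    duration = clip.samples.size / TARGET_RATE
    n_ticks = math.floor((duration - FRAME_SECONDS) * tick_hz) + 1
    for k in range(n_ticks):
        t = FRAME_SECONDS + k / tick_hz
        end = round(t * TARGET_RATE)
        end = min(end, clip.samples.size)
        yield t, Frame(samples=clip.samples[end - FRAME_SAMPLES : end], index=k)


def frames_to_tsv(frames: list[Frame], path: str | Path) -> None:
    """Dump per-frame index, start time and RMS as TSV for debugging."""
    import pandas as pd

    rows = [
        {"index": f.index, "start_s": f.start_s, "rms": float(np.sqrt(np.mean(f.samples**2)))}
        for f in frames
    ]
    pd.DataFrame(rows, columns=["index", "start_s", "rms"]).to_csv(
        path, sep="\t", index=False
    )
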