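"""Log-mel spectrogram front end.

Each 3120-sample frame is tiled five times to 15,600 samples (0.975 s) —
the minimum input of the pretrained audio-event embedding network — and
converted to a 64-band log-mel patch: STFT with a 25 ms Hann window and
10 ms hop (400/160 samples at 16 kHz, no edge padding), magnitude
spectrogram, HTK-mel triangular filters spanning 125–7500 Hz, then
log(S + 0.001). For a 15,600-sample input the patch is 64 x 96.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_io import FRAME_SAMPLES, TARGET_RATE, Frame

TILE_COPIES = 5
TILED_SAMPLES = TILE_COPIES * FRAME_SAMPLES  # 15600
WINDOW_SAMPLES = 400  # 25 ms at 16 kHz
HOP_SAMPLES = 160  # 10 ms
FFT_LENGTH = 512
N_MELS = 64
MEL_FMIN = 125.0
MEL_FMAX = 7500.0
LOG_FLOOR = 0.001

__all__ = [
    "LogMelPatch",
    "TILED_SAMPLES",
    "tile_frame",
    "log_mel",
    "mel_filterbank",
]


@dataclass(frozen=True)
class LogMelPatch:
    """64 x T matrix of log mel-spectrogram energies, floor log(0.001)."""

    values: np.ndarray  # shape (N_MELS, T)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.shape[0] != N_MELS:
            raise ValueError(f"LogMelPatch must be {N_MELS} x T, got {values.shape}")
        object.__setattr__(self, "values", values)

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]


def tile_frame(frame: Frame) -> np.ndarray:
    """Repeat one 0.195 s frame 5x to the 15,600-sample network input.

    Tiling (rather than zero-padding) keeps quiet environments and
    distinct sound sources maximally separated in the spectrogram.
    """
    if frame.samples.size != FRAME_SAMPLES:
        raise ValueError(f"frame must have {FRAME_SAMPLES} samples")
    return np.tile(frame.samples, TILE_COPIES)


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int = N_MELS,
    n_fft: int = FFT_LENGTH,
    sample_rate: int = TARGET_RATE,
    fmin: float = MEL_FMIN,
    fmax: float = MEL_FMAX,
) -> np.ndarray:
    """Triangular HTK-mel filters, shape (n_mels, n_fft//2 + 1).

    Band edges are uniformly spaced on the HTK mel scale between fmin and
    fmax; each filter rises linearly from its lower edge to its center and
    falls to its upper edge (unnormalized peaks, as in the pretrained
    network's front end).
    """
    fft_freqs = np.linspace(0.0, sample_rate / 2.0, n_fft // 2 + 1)
    mel_edges = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_edges = np.asarray(_mel_to_hz(mel_edges))
    fb = np.zeros((n_mels, fft_freqs.size))
    for i in range(n_mels):
        lower, center, upper = hz_edges[i : i + 3]
        up = (fft_freqs - lower) / (center - lower)
        down = (upper - fft_freqs) / (upper - center)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


_FILTERBANK = mel_filterbank()
_WINDOW = np.hanning(WINDOW_SAMPLES + 1)[:-1]  # periodic Hann


def log_mel(waveform: np.ndarray) -> LogMelPatch:
    """Compute the 64-band log-mel patch of a 16 kHz waveform.

    Uses valid framing (no padding): T = floor((n - 400)/160) + 1 time
    steps. Every cell is at least log(0.001); silence hits the floor
    exactly.
    """
    waveform = np.asarray(waveform, dtype=np.float64)
    if waveform.ndim != 1 or waveform.size < WINDOW_SAMPLES:
        raise ValueError(
            f"waveform must be 1-D with at least {WINDOW_SAMPLES} samples"
        )
    n_steps = (waveform.size - WINDOW_SAMPLES) // HOP_SAMPLES + 1
    idx = np.arange(WINDOW_SAMPLES)[None, :] + HOP_SAMPLES * np.arange(n_steps)[:, None]
    frames = waveform[idx] * _WINDOW
    spectrum = np.abs(np.fft.rfft(frames, n=FFT_LENGTH, axis=1))  # magnitude
    mel = spectrum @ _FILTERBANK.T  # (T, 64)
    return LogMelPatch(values=np.log(mel.T + LOG_FLOOR))


def patch_to_csv(patch: LogMelPatch, path) -> None:
    """Dump a patch as a dense CSV (rows = mel bands) for inspection."""
    np.savetxt(path, patch.values, delimiter=",")
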