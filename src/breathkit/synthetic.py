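"""Seeded synthetic breathing audio with ground-truth labels.

No breathing recordings ship with this package, so the pipeline is
verified on synthetic sessions built from four acoustic archetypes whose
spectra are fixed, documented, and deliberately exaggerated relative to
real breathing (the goal is pipeline verification, not realism):

* inhalation — quiet noise band-passed to roughly 300–2000 Hz;
* acoustic exhalation — louder broadband noise with a gentle low-pass
  tilt and an onset/offset envelope;
* airflow exhalation — high-amplitude wind-like rumble (low-passed
  noise with at least 80% of its spectral energy below 500 Hz);
* nonbreathing — near-silent ambient noise, optionally interrupted by
  tones, chirps or click bursts standing in for environmental sounds.

Sessions follow the BPM-scaled guidance pattern with Gaussian jitter on
segment boundaries; every segment is recorded in a ground-truth label
track with subtype labels. All randomness derives from one config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import signal as sps

from .audio_io import FRAME_SAMPLES, TARGET_RATE, AudioClip, Frame
from .annotation import Interval, LabelTrack
from .decision import BreathPhase
from .session import guided_phase, pattern_for_bpm

#: training-split composition of the original model's dataset, usable as
#: a preset for ``synth_dataset`` (nonbreathing = environmental + lab).
TABLE1_TRAINING_COUNTS = {
    "exhalation_acoustic": 4574,
    "exhalation_airflow": 418,
    "inhalation": 2470,
    "nonbreathing": 9800 + 1952,
}

__all__ = [
    "SynthConfig",
    "SynthSession",
    "TABLE1_TRAINING_COUNTS",
    "synth_session",
    "synth_dataset",
    "synth_detection_stream",
]


@dataclass(frozen=True)
class SynthConfig:
    duration_s: float = 60.0
    bpm: float = 6.0
    airflow_probability: float = 0.2  # exhalation subtype mix
    inhalation_level: float = 0.05  # target RMS per archetype
    exhalation_acoustic_level: float = 0.15
    exhalation_airflow_level: float = 0.30
    event_level: float = 0.10
    ambient_level: float = 0.003
    event_rate: float = 0.3  # probability a pause hosts a nonbreathing event
    boundary_jitter_sd_s: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.airflow_probability, self.event_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        levels = (
            self.inhalation_level,
            self.exhalation_acoustic_level,
            self.exhalation_airflow_level,
            self.event_level,
            self.ambient_level,
        )
        if any(level < 0 for level in levels):
            raise ValueError("amplitude levels must be >= 0")
        if self.boundary_jitter_sd_s < 0:
            raise ValueError("boundary_jitter_sd_s must be >= 0")


@dataclass
class SynthSession:
    clip: AudioClip
    labels: LabelTrack
    config: SynthConfig


def _rms_scale(x: np.ndarray, target_rms: float) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2))
    return x * (target_rms / rms) if rms > 0 else x


def _envelope(n: int, edge_fraction: float = 0.15) -> np.ndarray:
    edge = max(1, int(n * edge_fraction))
    env = np.ones(n)
    ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, edge)))
    env[:edge] = ramp
    env[-edge:] = ramp[::-1]
    return env


_BP_INHALE = sps.butter(4, [300.0, 2000.0], btype="bandpass", fs=TARGET_RATE, output="sos")
_LP_ACOUSTIC = sps.butter(2, 4000.0, btype="lowpass", fs=TARGET_RATE, output="sos")
_LP_AIRFLOW = sps.butter(6, 220.0, btype="lowpass", fs=TARGET_RATE, output="sos")


def _gen_inhalation(rng: np.random.Generator, n: int, cfg: SynthConfig) -> np.ndarray:
    noise = sps.sosfilt(_BP_INHALE, rng.standard_normal(n))
    return _rms_scale(noise, cfg.inhalation_level) * _envelope(n)


def _gen_exhalation_acoustic(rng: np.random.Generator, n: int, cfg: SynthConfig) -> np.ndarray:
    noise = sps.sosfilt(_LP_ACOUSTIC, rng.standard_normal(n))
    return _rms_scale(noise, cfg.exhalation_acoustic_level) * _envelope(n)


def _gen_exhalation_airflow(rng: np.random.Generator, n: int, cfg: SynthConfig) -> np.ndarray:
    noise = sps.sosfilt(_LP_AIRFLOW, rng.standard_normal(n))
    return _rms_scale(noise, cfg.exhalation_airflow_level) * _envelope(n)


def _gen_event(rng: np.random.Generator, n: int, cfg: SynthConfig) -> np.ndarray:
    t = np.arange(n) / TARGET_RATE
    kind = rng.integers(3)
    if kind == 0:  # steady tone
        f = rng.uniform(500.0, 4000.0)
        x = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    elif kind == 1:  # linear chirp
        f0, f1 = sorted(rng.uniform(400.0, 5000.0, size=2))
        x = sps.chirp(t, f0=f0, f1=f1, t1=t[-1] if n > 1 else 1.0)
    else:  # click bursts
        x = np.zeros(n)
        for _ in range(max(1, n // 1600)):
            pos = rng.integers(0, max(1, n - 80))
            x[pos : pos + 80] += rng.standard_normal(80)
    return _rms_scale(x, cfg.event_level) * _envelope(n)


_GENERATORS: dict[str, Callable] = {
    "inhalation": _gen_inhalation,
    "exhalation_acoustic": _gen_exhalation_acoustic,
    "exhalation_airflow": _gen_exhalation_airflow,
}


def synth_session(cfg: SynthConfig) -> SynthSession:
    """Generate one breathing session: 16 kHz audio plus its label track.

    Cycle segments follow ``pattern_for_bpm(cfg.bpm)`` with Gaussian
    boundary jitter; exhalation subtype is drawn per cycle; pauses carry
    ambient noise and, at ``event_rate``, a nonbreathing event. Identical
    configs (including seed) give bit-identical output.
    """
    pattern = pattern_for_bpm(cfg.bpm)
    if cfg.duration_s < pattern.cycle_s:
        raise ValueError("duration must cover at least one breathing cycle")
    ss = np.random.SeedSequence(cfg.seed)
    rng_plan, rng_sound, rng_ambient = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )

    n_total = int(round(cfg.duration_s * TARGET_RATE))
    audio = rng_ambient.standard_normal(n_total) * cfg.ambient_level
    intervals: list[Interval] = []

    def jitter(d: float) -> float:
        return max(0.05, d + rng_plan.normal(0.0, cfg.boundary_jitter_sd_s))

    t = 0.0
    while True:
        subtype = (
            "exhalation_airflow"
            if rng_plan.random() < cfg.airflow_probability
            else "exhalation_acoustic"
        )
        segments = [
            ("inhalation", jitter(pattern.inhale_s)),
            ("pause", jitter(pattern.pause1_s)),
            (subtype, jitter(pattern.exhale_s)),
            ("pause", pattern.pause2_s),
        ]
        if t + sum(d for _, d in segments) > cfg.duration_s:
            break
        for kind, dur in segments:
            if dur <= 0:
                continue
            start = int(round(t * TARGET_RATE))
            end = min(int(round((t + dur) * TARGET_RATE)), n_total)
            n = end - start
            if n <= 0:
                t += dur
                continue
            if kind == "pause":
                intervals.append(Interval(t, t + dur, "nonbreathing"))
                if rng_plan.random() < cfg.event_rate and n > 160:
                    audio[start:end] += _gen_event(rng_sound, n, cfg)
            else:
                intervals.append(Interval(t, t + dur, kind))
                audio[start:end] += _GENERATORS[kind](rng_sound, n, cfg)
            t += dur
    # tail after the last whole cycle stays ambient-only nonbreathing
    if t < cfg.duration_s - 1e-9:
        intervals.append(Interval(t, cfg.duration_s, "nonbreathing"))

    audio = np.clip(audio, -1.0, 1.0)
    return SynthSession(
        clip=AudioClip(samples=audio, sample_rate=TARGET_RATE),
        labels=LabelTrack(intervals=tuple(intervals), duration_s=cfg.duration_s),
        config=cfg,
    )


def synth_dataset(
    cfg: SynthConfig, class_counts: dict[str, int]
) -> tuple[list[Frame], list[str], list[BreathPhase]]:
    """Generate single-class frames with exact per-class counts.

    ``class_counts`` maps subtype labels (exhalation_acoustic,
    exhalation_airflow, inhalation, nonbreathing) to requested frame
    counts; pass ``TABLE1_TRAINING_COUNTS`` to mirror the original
    training-set composition. Nonbreathing frames alternate between
    ambient noise and events according to ``cfg.event_rate``. Returns
    (frames, subtype labels, collapsed phases).
    """
    if any(c < 0 for c in class_counts.values()):
        raise ValueError("requested counts must be >= 0")
    unknown = set(class_counts) - (set(_GENERATORS) | {"nonbreathing"})
    if unknown:
        raise ValueError(f"unknown classes requested: {sorted(unknown)}")
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    frames: list[Frame] = []
    labels: list[str] = []
    phases: list[BreathPhase] = []
    phase_of = {
        "inhalation": BreathPhase.INHALATION,
        "exhalation_acoustic": BreathPhase.EXHALATION,
        "exhalation_airflow": BreathPhase.EXHALATION,
        "nonbreathing": BreathPhase.NONBREATHING,
    }
    for label in sorted(class_counts):
        for _ in range(class_counts[label]):
            if label == "nonbreathing":
                if rng.random() < cfg.event_rate:
                    samples = _gen_event(rng, FRAME_SAMPLES, cfg)
                else:
                    samples = rng.standard_normal(FRAME_SAMPLES) * cfg.ambient_level
            else:
                samples = _GENERATORS[label](rng, FRAME_SAMPLES, cfg)
            frames.append(Frame(samples=np.clip(samples, -1, 1), index=len(frames)))
            labels.append(label)
            phases.append(phase_of[label])
    return frames, labels, phases


def synth_detection_stream(
    cfg: SynthConfig,
    error_model: dict[BreathPhase, dict[BreathPhase, float]] | None = None,
    tick_hz: float = 30.0,
) -> list[tuple[float, BreathPhase]]:
    """Guided phases at tick_hz corrupted by per-class confusion probabilities.

    ``error_model`` maps each true phase to an output distribution over
    phases; missing phases pass through unchanged. Drives heuristic and
    session tests without synthesizing audio.
    """
    pattern = pattern_for_bpm(cfg.bpm)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    phases = [BreathPhase.EXHALATION, BreathPhase.INHALATION, BreathPhase.NONBREATHING]
    stream = []
    n_ticks = int(np.floor(cfg.duration_s * tick_hz)) + 1
    for k in range(n_ticks):
        t = k / tick_hz
        true = guided_phase(pattern, t)
        out = true
        if error_model and true in error_model:
            dist = error_model[true]
            probs = np.array([dist.get(p, 0.0) for p in phases])
            if np.any(probs < 0) or np.any(probs > 1) or probs.sum() > 1 + 1e-9:
                raise ValueError("error-model probabilities must lie in [0, 1]")
            probs = probs / probs.sum() if abs(probs.sum() - 1) > 1e-9 else probs
            out = phases[rng.choice(3, p=probs)]
        stream.append((t, out))
    return stream
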