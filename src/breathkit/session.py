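"""Paced-breathing session guidance, feedback dynamics and scoring.

A session guides the user through inhalation–pause–exhalation–pause
cycles. The canonical pattern at 6 breaths per minute (BPM) is
4-1-5-0 seconds; for other rates the pauses stay fixed at (1, 0) and
the remaining 60/bpm − 1 seconds are split 4:5 between inhalation and
exhalation — the unique linear scaling consistent with both canonical
patterns (6 BPM → 4-1-5-0, 7 BPM → 3.37-1-4.21-0).

The visual feedback is a sailboat: it accelerates while the detector
reports exhalation during a guided exhalation and otherwise relaxes
exponentially back to a constant base speed. A session is scored by the
distance covered and by exhalation accuracy — the fraction of guided-
exhalation ticks on which the (smoothed) detector reported exhalation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .decision import BreathPhase
from .heuristic import HeuristicConfig, apply_heuristic

__all__ = [
    "BreathingPattern",
    "SessionConfig",
    "SessionTrace",
    "SessionScore",
    "pattern_for_bpm",
    "guided_phase",
    "feedback_step",
    "run_session",
]

DURATION_PRESETS_S = {"beginner": 120.0, "intermediate": 180.0, "expert": 300.0}

_INHALE_WEIGHT = 4.0
_EXHALE_WEIGHT = 5.0


@dataclass(frozen=True)
class BreathingPattern:
    """Cycle durations (s): inhale, pause, exhale, pause; sums to 60/bpm."""

    inhale_s: float
    pause1_s: float
    exhale_s: float
    pause2_s: float
    bpm: float

    def __post_init__(self) -> None:
        durations = (self.inhale_s, self.pause1_s, self.exhale_s, self.pause2_s)
        if any(d < 0 for d in durations):
            raise ValueError("phase durations must be non-negative")
        if abs(sum(durations) - 60.0 / self.bpm) > 1e-9:
            raise ValueError("pattern durations must sum to 60/bpm")

    @property
    def cycle_s(self) -> float:
        return 60.0 / self.bpm


@dataclass(frozen=True)
class SessionConfig:
    duration_s: float = DURATION_PRESETS_S["beginner"]
    bpm: float = 6.0
    base_speed: float = 1.0
    accel: float = 2.0
    max_speed: float = 4.0
    decay_rate: float = 1.0
    tick_hz: float = 30.0
    heuristic: HeuristicConfig | None = field(default_factory=HeuristicConfig)

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.bpm <= 0 or self.tick_hz <= 0:
            raise ValueError("duration_s, bpm and tick_hz must be positive")


@dataclass
class SessionTrace:
    frame: pd.DataFrame  # columns: t, guided, raw, smoothed, speed, distance


@dataclass(frozen=True)
class SessionScore:
    distance: float
    exhalation_accuracy: float


def pattern_for_bpm(bpm: float) -> BreathingPattern:
    """Scale the 4-1-5-0 pattern linearly to a target breathing rate.

    Pauses are held at (1, 0) s; inhalation and exhalation share the
    remaining 60/bpm − 1 seconds in ratio 4:5.
    """
    if bpm <= 0 or 60.0 / bpm <= 1.0:
        raise ValueError("bpm must leave more than the 1 s pause per cycle (60/bpm > 1)")
    active = 60.0 / bpm - 1.0
    total_weight = _INHALE_WEIGHT + _EXHALE_WEIGHT
    inhale = active * _INHALE_WEIGHT / total_weight
    return BreathingPattern(
        inhale_s=inhale,
        pause1_s=1.0,
        exhale_s=active - inhale,
        pause2_s=0.0,
        bpm=bpm,
    )


def guided_phase(pattern: BreathingPattern, t: float) -> BreathPhase:
    """Guided phase at time t (cycle-periodic); pauses map to NONBREATHING."""
    if t < 0:
        raise ValueError("t must be >= 0")
    tau = t % pattern.cycle_s
    if tau < pattern.inhale_s:
        return BreathPhase.INHALATION
    if tau < pattern.inhale_s + pattern.pause1_s:
        return BreathPhase.NONBREATHING
    if tau < pattern.inhale_s + pattern.pause1_s + pattern.exhale_s:
        return BreathPhase.EXHALATION
    return BreathPhase.NONBREATHING


def feedback_step(
    speed: float,
    guided: BreathPhase,
    detected: BreathPhase,
    dt: float,
    cfg: SessionConfig,
) -> float:
    """One Euler step of the sailboat speed.

    Accelerates (clamped at max_speed) while a guided exhalation is
    matched by a detected exhalation; otherwise decays exponentially
    toward base_speed.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if guided is BreathPhase.EXHALATION and detected is BreathPhase.EXHALATION:
        return min(speed + cfg.accel * dt, cfg.max_speed)
    return cfg.base_speed + (speed - cfg.base_speed) * float(np.exp(-cfg.decay_rate * dt))


def run_session(
    detected: Iterable[tuple[float, BreathPhase]],
    cfg: SessionConfig,
) -> tuple[SessionTrace, SessionScore]:
    """Run the feedback loop over a timestamped raw-detection stream.

    The stream must cover [0, duration_s]; ticks after duration_s are
    ignored. The exhalation-hold heuristic (cfg.heuristic, None to
    disable) smooths raw calls before they drive the boat. Distance is
    the Euler integral of speed; exhalation accuracy is guided-exhalation
    coverage by smoothed exhalation calls.
    """
    pattern = pattern_for_bpm(cfg.bpm)
    events = [(t, raw) for t, raw in detected if t <= cfg.duration_s]
    if not events:
        raise ValueError("detection stream is empty")
    times = [t for t, _ in events]
    raw_phases = [p for _, p in events]
    if cfg.heuristic is not None:
        smoothed = [p for _, p in apply_heuristic(events, cfg.heuristic)]
    else:
        smoothed = list(raw_phases)

    rows = []
    speed = cfg.base_speed
    distance = 0.0
    prev_t = 0.0
    for t, raw, smooth in zip(times, raw_phases, smoothed):
        dt = t - prev_t
        guided = guided_phase(pattern, t)
        if dt > 0:
            speed = feedback_step(speed, guided, smooth, dt, cfg)
            distance += speed * dt
        rows.append(
            {
                "t": t,
                "guided": guided.value,
                "raw": raw.value,
                "smoothed": smooth.value,
                "speed": speed,
                "distance": distance,
            }
        )
        prev_t = t

    frame = pd.DataFrame(rows)
    exh_mask = frame["guided"] == BreathPhase.EXHALATION.value
    n_guided = int(exh_mask.sum())
    hits = int((exh_mask & (frame["smoothed"] == BreathPhase.EXHALATION.value)).sum())
    accuracy = hits / n_guided if n_guided else float("nan")
    return SessionTrace(frame=frame), SessionScore(
        distance=float(distance), exhalation_accuracy=float(accuracy)
    )
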