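"""Exhalation-hold smoothing of streamed phase calls.

The feedback loop centers on exhalations, and raw per-frame calls can
flicker. After every raw EXHALATION detection the output phase is held
at EXHALATION for a configurable duration (default 300 ms); each new raw
exhalation resets the hold. A call arriving exactly at hold expiry uses
the raw phase (strict comparison). The heuristic operates on phase calls
with explicit timestamps, never on probabilities, and can only add
exhalation output — it never suppresses one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

from .decision import BreathPhase

DEFAULT_HOLD_S = 0.3

__all__ = [
    "HeuristicConfig",
    "HeuristicState",
    "heuristic_step",
    "apply_heuristic",
]


@dataclass(frozen=True)
class HeuristicConfig:
    hold_duration_s: float = DEFAULT_HOLD_S

    def __post_init__(self) -> None:
        if self.hold_duration_s < 0:
            raise ValueError("hold_duration_s must be >= 0")


@dataclass(frozen=True)
class HeuristicState:
    hold_until_s: float = -math.inf
    last_input_time_s: float = -math.inf


def heuristic_step(
    state: HeuristicState,
    raw: BreathPhase,
    t: float,
    cfg: HeuristicConfig = HeuristicConfig(),
) -> tuple[BreathPhase, HeuristicState]:
    """Advance the hold state by one timestamped raw call."""
    if t <= state.last_input_time_s:
        raise ValueError("time must advance strictly between heuristic steps")
    if raw is BreathPhase.EXHALATION:
        return raw, HeuristicState(
            hold_until_s=t + cfg.hold_duration_s, last_input_time_s=t
        )
    if t < state.hold_until_s:
        return BreathPhase.EXHALATION, HeuristicState(
            hold_until_s=state.hold_until_s, last_input_time_s=t
        )
    return raw, HeuristicState(hold_until_s=state.hold_until_s, last_input_time_s=t)


def apply_heuristic(
    stream: Iterable[tuple[float, BreathPhase]],
    cfg: HeuristicConfig = HeuristicConfig(),
) -> Iterator[tuple[float, BreathPhase]]:
    """Fold :func:`heuristic_step` over a (t, raw-phase) stream."""
    state = HeuristicState()
    for t, raw in stream:
        smoothed, state = heuristic_step(state, raw, t, cfg)
        yield t, smoothed
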