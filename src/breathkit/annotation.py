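"""Interval label tracks, two-rater merging, agreement, frame projection.

Ground truth for breathing audio is annotated as half-open time
intervals labeled exhalation_acoustic, exhalation_airflow, inhalation,
nonbreathing or unclear; unlabeled gaps count implicitly as
nonbreathing. Two raters' tracks are merged by averaging boundaries that
agree to within 200 ms; larger disagreements are flagged for manual
resolution, and class conflicts over the same span become `unclear`
rather than inventing agreement. Inter-rater reliability is Cohen's
kappa on the detector's 0.195 s frame grid over the three detector
classes. Tracks also project onto that frame grid to build labeled
datasets: each frame takes the label with the largest temporal overlap
(exhalation subtypes collapse), and any contact with `unclear` masks the
frame out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .audio_io import FRAME_SECONDS
from .decision import BreathPhase

VALID_LABELS = (
    "exhalation_acoustic",
    "exhalation_airflow",
    "inhalation",
    "nonbreathing",
    "unclear",
)
BOUNDARY_TOLERANCE_S = 0.2

_LABEL_TO_PHASE = {
    "exhalation_acoustic": BreathPhase.EXHALATION,
    "exhalation_airflow": BreathPhase.EXHALATION,
    "inhalation": BreathPhase.INHALATION,
    "nonbreathing": BreathPhase.NONBREATHING,
    "unclear": BreathPhase.UNCLEAR,
}
# tie-break priority when overlaps are equal
_PHASE_PRIORITY = {
    BreathPhase.EXHALATION: 0,
    BreathPhase.INHALATION: 1,
    BreathPhase.NONBREATHING: 2,
}

__all__ = [
    "Interval",
    "LabelTrack",
    "MergeReport",
    "AgreementReport",
    "read_label_tsv",
    "write_label_tsv",
    "merge_raters",
    "frame_labels",
    "cohen_kappa",
]


@dataclass(frozen=True)
class Interval:
    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"interval must have start < end, got {self}")
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def phase(self) -> BreathPhase:
        return _LABEL_TO_PHASE[self.label]


@dataclass(frozen=True)
class LabelTrack:
    """Time-ordered, non-overlapping labeled intervals over [0, duration]."""

    intervals: tuple[Interval, ...]
    duration_s: float

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.intervals, key=lambda iv: iv.start_s))
        for a, b in zip(ordered, ordered[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValueError(f"intervals overlap: {a} and {b}")
        if ordered and ordered[-1].end_s > self.duration_s + 1e-9:
            raise ValueError("intervals extend past the track duration")
        object.__setattr__(self, "intervals", ordered)


@dataclass
class MergeReport:
    merged: LabelTrack
    flagged: list[dict] = field(default_factory=list)  # >200 ms boundary pairs
    conflicts: list[dict] = field(default_factory=list)  # class disagreements


@dataclass(frozen=True)
class AgreementReport:
    p_observed: float
    p_expected: float
    kappa: float
    n_frames: int


def read_label_tsv(path: str | Path, duration_s: float | None = None) -> LabelTrack:
    """Read a label track TSV with columns start_s, end_s, label."""
    df = pd.read_csv(path, sep="\t")
    intervals = tuple(
        Interval(float(r.start_s), float(r.end_s), str(r.label))
        for r in df.itertuples(index=False)
    )
    if duration_s is None:
        duration_s = max((iv.end_s for iv in intervals), default=0.0)
    return LabelTrack(intervals=intervals, duration_s=duration_s)


def write_label_tsv(track: LabelTrack, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"start_s": iv.start_s, "end_s": iv.end_s, "label": iv.label}
            for iv in track.intervals
        ],
        columns=["start_s", "end_s", "label"],
    ).to_csv(path, sep="\t", index=False)


def _overlap(a: Interval, b: Interval) -> float:
    return max(0.0, min(a.end_s, b.end_s) - max(a.start_s, b.start_s))


def merge_raters(a: LabelTrack, b: LabelTrack) -> MergeReport:
    """Merge two raters' tracks into one consensus track.

    Intervals are paired across tracks by maximal temporal overlap. For a
    pair whose start and end both agree to within 200 ms, the merged
    interval averages the boundaries; a class disagreement yields label
    `unclear` and a conflict record. Pairs with a boundary difference
    over 200 ms are flagged for manual resolution and excluded from the
    merged track. An interval only one rater drew disagrees with the
    other rater's implicit nonbreathing gap, so it is merged as `unclear`
    unless it is itself nonbreathing.
    """
    if abs(a.duration_s - b.duration_s) > 1e-6:
        raise ValueError("tracks must cover the same duration")

    used_b: set[int] = set()
    merged: list[Interval] = []
    flagged: list[dict] = []
    conflicts: list[dict] = []

    for iv_a in a.intervals:
        candidates = [
            (j, _overlap(iv_a, iv_b))
            for j, iv_b in enumerate(b.intervals)
            if j not in used_b and _overlap(iv_a, iv_b) > 0
        ]
        if not candidates:
            _merge_unmatched(iv_a, "a", merged, conflicts)
            continue
        j = max(candidates, key=lambda c: c[1])[0]
        used_b.add(j)
        iv_b = b.intervals[j]
        d_start = abs(iv_a.start_s - iv_b.start_s)
        d_end = abs(iv_a.end_s - iv_b.end_s)
        if d_start > BOUNDARY_TOLERANCE_S or d_end > BOUNDARY_TOLERANCE_S:
            flagged.append(
                {
                    "a": (iv_a.start_s, iv_a.end_s, iv_a.label),
                    "b": (iv_b.start_s, iv_b.end_s, iv_b.label),
                    "start_diff_s": d_start,
                    "end_diff_s": d_end,
                }
            )
            continue
        start = (iv_a.start_s + iv_b.start_s) / 2.0
        end = (iv_a.end_s + iv_b.end_s) / 2.0
        if iv_a.label == iv_b.label:
            label = iv_a.label
        else:
            label = "unclear"
            conflicts.append(
                {
                    "span": (start, end),
                    "a_label": iv_a.label,
                    "b_label": iv_b.label,
                }
            )
        merged.append(Interval(start, end, label))

    for j, iv_b in enumerate(b.intervals):
        if j not in used_b:
            _merge_unmatched(iv_b, "b", merged, conflicts)

    duration = a.duration_s
    return MergeReport(
        merged=LabelTrack(intervals=tuple(merged), duration_s=duration),
        flagged=flagged,
        conflicts=conflicts,
    )


def _merge_unmatched(
    iv: Interval, rater: str, merged: list[Interval], conflicts: list[dict]
) -> None:
    if iv.label == "nonbreathing":  # agrees with the other rater's implicit gap
        merged.append(iv)
        return
    merged.append(Interval(iv.start_s, iv.end_s, "unclear"))
    conflicts.append(
        {
            "span": (iv.start_s, iv.end_s),
            "a_label": iv.label if rater == "a" else "nonbreathing",
            "b_label": iv.label if rater == "b" else "nonbreathing",
        }
    )


def frame_labels(
    track: LabelTrack, n_frames: int, frame_s: float = FRAME_SECONDS
) -> tuple[list[BreathPhase], np.ndarray]:
    """Project a label track onto the detector frame grid.

    Frame i covers [i*frame_s, (i+1)*frame_s) and receives the phase with
    the largest temporal overlap (gaps count as nonbreathing, exhalation
    subtypes collapse). Any overlap with `unclear` masks the frame out.
    Equal overlaps break by priority exhalation > inhalation >
    nonbreathing. Returns (phases, mask) where mask[i] is True for
    scorable frames.
    """
    if track.duration_s + 1e-9 < n_frames * frame_s:
        raise ValueError("track shorter than the requested frame grid")
    phases: list[BreathPhase] = []
    mask = np.ones(n_frames, dtype=bool)
    for i in range(n_frames):
        f = Interval(i * frame_s, (i + 1) * frame_s, "nonbreathing")
        overlaps = {
            BreathPhase.EXHALATION: 0.0,
            BreathPhase.INHALATION: 0.0,
            BreathPhase.NONBREATHING: 0.0,
        }
        covered = 0.0
        unclear_touch = False
        for iv in track.intervals:
            if iv.end_s <= f.start_s or iv.start_s >= f.end_s:
                continue
            ov = _overlap(f, iv)
            covered += ov
            if iv.phase is BreathPhase.UNCLEAR:
                if ov > 1e-9:
                    unclear_touch = True
            else:
                overlaps[iv.phase] += ov
        overlaps[BreathPhase.NONBREATHING] += max(0.0, frame_s - covered)  # gaps
        if unclear_touch:
            mask[i] = False
            phases.append(BreathPhase.UNCLEAR)
            continue
        best = max(
            overlaps.items(), key=lambda kv: (kv[1], -_PHASE_PRIORITY[kv[0]])
        )[0]
        phases.append(best)
    return phases, mask


def cohen_kappa(
    a_frames: list[BreathPhase],
    b_frames: list[BreathPhase],
    a_mask: np.ndarray | None = None,
    b_mask: np.ndarray | None = None,
) -> AgreementReport:
    """Multi-class Cohen kappa between two frame-label sequences.

    Frames masked out for either rater are removed pairwise before the
    cross-tabulation. kappa = (p_o − p_e) / (1 − p_e).
    """
    if len(a_frames) != len(b_frames):
        raise ValueError("frame sequences must have equal length")
    keep = np.ones(len(a_frames), dtype=bool)
    if a_mask is not None:
        keep &= np.asarray(a_mask, dtype=bool)
    if b_mask is not None:
        keep &= np.asarray(b_mask, dtype=bool)
    a_kept = [p for p, k in zip(a_frames, keep) if k]
    b_kept = [p for p, k in zip(b_frames, keep) if k]
    n = len(a_kept)
    if n == 0:
        raise ValueError("no scorable frames in common")
    classes = sorted({p.value for p in a_kept} | {p.value for p in b_kept})
    idx = {c: i for i, c in enumerate(classes)}
    table = np.zeros((len(classes), len(classes)))
    for pa, pb in zip(a_kept, b_kept):
        table[idx[pa.value], idx[pb.value]] += 1
    p_o = float(np.trace(table) / n)
    p_e = float(np.sum(table.sum(axis=1) * table.sum(axis=0)) / n**2)
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return AgreementReport(p_observed=p_o, p_expected=p_e, kappa=float(kappa), n_frames=n)
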