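"""Run/pause segmentation and directionality classification of oriented tracks.

A traced track is a polyline of (time, position) vertices.  Each consecutive
vertex pair is one *segment* with a well-defined speed.  Segments with
|speed| below the static threshold (default 25 nm/s) are *static*; maximal
stretches of same-direction moving segments are *runs*, maximal static
stretches are *pauses*.  A run therefore ends when the motor falls static or
reverses direction.

Overall directionality is assigned by rules applied in a fixed order:

1. total run length (sum of |run length| over all runs) < 1,000 nm -> static;
2. runs in only one direction -> that direction;
3. more than 1,500 nm of run length in *both* directions -> bidirectional;
4. otherwise the majority direction wins, however small the margin (a track
   with 20,000 nm minus and 200 nm plus run length is minus-end directed).

All inequalities are strict as stated: |speed| exactly at the static
threshold counts as moving; exactly 1,000 nm total is not static; exactly
1,500 nm each way is not bidirectional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

from kymotility.io_model import Track

__all__ = [
    "Segment",
    "Run",
    "Pause",
    "TrackClassification",
    "compute_segments",
    "segment_runs",
    "classify_track",
    "STATIC_SPEED_NM_S",
    "STATIC_TOTAL_NM",
    "BIDIRECTIONAL_NM",
]

#: Default thresholds (nm/s and nm) for the static/run/class rules.
STATIC_SPEED_NM_S = 25.0
STATIC_TOTAL_NM = 1000.0
BIDIRECTIONAL_NM = 1500.0

Direction = Literal["plus", "minus"]


@dataclass(frozen=True)
class Segment:
    """One vertex-to-vertex piece of a track."""

    dt: float
    dx: float

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"segment duration must be positive, got {self.dt}")

    @property
    def speed(self) -> float:
        """Signed speed in nm/s (positive toward the plus end)."""
        return self.dx / self.dt


@dataclass(frozen=True)
class Run:
    """A maximal unidirectional moving stretch."""

    direction: Direction
    length_nm: float       # sum of |dx| over member segments
    duration_s: float
    signed_length_nm: float


@dataclass(frozen=True)
class Pause:
    """A maximal static stretch (every member segment below the speed threshold)."""

    duration_s: float
    drift_nm: float        # net displacement while static


@dataclass(frozen=True)
class TrackClassification:
    label: Literal["static", "plus", "minus", "bidirectional"]
    plus_total_nm: float
    minus_total_nm: float

    @property
    def total_run_length_nm(self) -> float:
        return self.plus_total_nm + self.minus_total_nm


def compute_segments(track: Track) -> list[Segment]:
    """Split an oriented track into per-vertex-pair segments.

    The segment durations sum to the track duration and the displacements
    sum to the net displacement, by construction.
    """
    return [
        Segment(dt=b.t - a.t, dx=b.x - a.x)
        for a, b in zip(track.vertices, track.vertices[1:])
    ]


def segment_runs(
    segments: Sequence[Segment],
    static_speed_nm_s: float = STATIC_SPEED_NM_S,
) -> tuple[list[Run], list[Pause]]:
    """Partition segments into runs and pauses.

    A segment is static iff |speed| < *static_speed_nm_s*.  Consecutive
    moving segments of equal sign merge into one run; a run ends at a static
    segment or at a direction reversal.  Every segment belongs to exactly
    one run or pause, so run and pause durations sum to the track duration.
    """
    if not segments:
        raise ValueError("segment list is empty")
    runs: list[Run] = []
    pauses: list[Pause] = []
    # state: None, "pause", or +1/-1 for the current run direction
    state: int | str | None = None
    dt_acc = dx_acc = abs_acc = 0.0

    def flush() -> None:
        nonlocal dt_acc, dx_acc, abs_acc
        if state == "pause":
            pauses.append(Pause(duration_s=dt_acc, drift_nm=dx_acc))
        elif state is not None:
            direction: Direction = "plus" if state > 0 else "minus"
            runs.append(
                Run(direction=direction, length_nm=abs_acc, duration_s=dt_acc, signed_length_nm=dx_acc)
            )
        dt_acc = dx_acc = abs_acc = 0.0

    for seg in segments:
        if abs(seg.speed) < static_speed_nm_s:
            nxt: int | str = "pause"
        else:
            nxt = 1 if seg.speed > 0 else -1
        if nxt != state:
            flush()
            state = nxt
        dt_acc += seg.dt
        dx_acc += seg.dx
        abs_acc += abs(seg.dx)
    flush()
    return runs, pauses


def classify_track(
    runs: Sequence[Run],
    static_total_nm: float = STATIC_TOTAL_NM,
    bidirectional_nm: float = BIDIRECTIONAL_NM,
) -> TrackClassification:
    """Classify overall directionality from a track's runs.

    Rules are applied in order: static (< *static_total_nm* total run
    length), single-direction, bidirectional (> *bidirectional_nm* both
    ways), then majority direction.
    """
    plus_total = sum(r.length_nm for r in runs if r.direction == "plus")
    minus_total = sum(r.length_nm for r in runs if r.direction == "minus")
    total = plus_total + minus_total
    if total < static_total_nm:
        label = "static"
    elif minus_total == 0:
        label = "plus"
    elif plus_total == 0:
        label = "minus"
    elif plus_total > bidirectional_nm and minus_total > bidirectional_nm:
        label = "bidirectional"
    elif plus_total > minus_total:
        label = "plus"
    elif minus_total > plus_total:
        label = "minus"
    else:
        # Exact plus/minus tie below the bidirectional cut: any directional
        # choice would be arbitrary, so call it bidirectional and warn.
        warnings.warn(
            "exact plus/minus run-length tie; classifying as bidirectional",
            stacklevel=2,
        )
        label = "bidirectional"
    return TrackClassification(label=label, plus_total_nm=plus_total, minus_total_nm=minus_total)
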