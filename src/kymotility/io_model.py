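"""Core data model and CSV I/O for traced motor tracks.

Coordinate convention: after orientation, ``x`` is the position along the
microtubule axis in nanometers, positive toward the plus end; ``t`` is time
in seconds from movie start.  Thresholds used downstream (static speed,
classification cut-offs) are all stated in these units, so any pixel/frame
data must be converted at read time using the kymograph context's
``pixel_size_nm`` and ``frame_interval_s``.

Track tables are plain CSV with one row per traced vertex
(``track_id, context_id, t_s, x_nm``); kymograph contexts and the
experiment manifest live in separate CSV tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "TrackVertex",
    "Track",
    "KymographContext",
    "ExperimentManifest",
    "read_tracks",
    "write_tracks",
    "read_contexts",
    "write_contexts",
    "read_manifest",
    "write_manifest",
    "orient_track",
]

Polarity = Literal["plus_right", "plus_left", "unknown"]

TRACK_COLUMNS = ["track_id", "context_id", "t_s", "x_nm"]
CONTEXT_COLUMNS = [
    "context_id",
    "mt_length_nm",
    "duration_s",
    "pixel_size_nm",
    "frame_interval_s",
    "polarity",
]
MANIFEST_COLUMNS = ["condition", "experiment_id", "movie_id", "context_id", "track_id"]


@dataclass(frozen=True)
class TrackVertex:
    """One traced point of a motor track: time (s) and position (nm)."""

    t: float
    x: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.t) or self.t < 0:
            raise ValueError(f"vertex time must be finite and non-negative, got {self.t}")
        if not math.isfinite(self.x):
            raise ValueError(f"vertex position must be finite, got {self.x}")


@dataclass(frozen=True)
class Track:
    """An ordered polyline of traced vertices for one motor complex."""

    track_id: str
    vertices: tuple[TrackVertex, ...]
    context_id: str

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise ValueError(f"track {self.track_id!r} needs >=2 vertices, got {len(self.vertices)}")
        ts = [v.t for v in self.vertices]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"track {self.track_id!r} has non-monotone time")

    @property
    def duration_s(self) -> float:
        return self.vertices[-1].t - self.vertices[0].t

    @property
    def net_displacement_nm(self) -> float:
        return self.vertices[-1].x - self.vertices[0].x


@dataclass(frozen=True)
class KymographContext:
    """Geometry and acquisition metadata for one kymograph (one microtubule).

    Parameters
    ----------
    mt_length_nm
        Microtubule (kymograph spatial width) in nanometers.
    duration_s
        Movie length in seconds.
    pixel_size_nm, frame_interval_s
        Camera sampling; used to convert pixel/frame traces to nm/s.
    polarity
        Which image direction points to the microtubule plus end, as
        established by a plus-end-motor polarity check.
    """

    context_id: str
    mt_length_nm: float
    duration_s: float
    pixel_size_nm: float
    frame_interval_s: float
    polarity: Polarity = "unknown"

    def __post_init__(self) -> None:
        for name in ("mt_length_nm", "duration_s", "pixel_size_nm", "frame_interval_s"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"context {self.context_id!r}: {name} must be positive, got {v}")
        if self.polarity not in ("plus_right", "plus_left", "unknown"):
            raise ValueError(f"context {self.context_id!r}: bad polarity {self.polarity!r}")


@dataclass
class ExperimentManifest:
    """Maps every track to its microtubule, movie, experiment and condition."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=MANIFEST_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        dup = self.table["track_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"manifest maps track(s) {sorted(self.table.loc[dup, 'track_id'])} more than once"
            )

    def lookup(self, track_id: str) -> pd.Series:
        rows = self.table[self.table["track_id"] == track_id]
        if rows.empty:
            raise KeyError(f"track {track_id!r} not in manifest")
        return rows.iloc[0]

    def group_of(self, track_ids: Sequence[str], level: str) -> pd.Series:
        """Return the grouping key (condition/experiment/movie/context) per track."""
        col = {
            "condition": "condition",
            "experiment": "experiment_id",
            "movie": "movie_id",
            "mt": "context_id",
            "microtubule": "context_id",
        }[level]
        idx = self.table.set_index("track_id")[col]
        missing = [t for t in track_ids if t not in idx.index]
        if missing:
            raise KeyError(f"track(s) {missing[:5]} not in manifest")
        return idx.loc[list(track_ids)]


def _validate_contexts(contexts: Iterable[KymographContext]) -> dict[str, KymographContext]:
    out: dict[str, KymographContext] = {}
    for c in contexts:
        if c.context_id in out:
            raise ValueError(f"duplicate context_id {c.context_id!r}")
        out[c.context_id] = c
    return out


def read_tracks(
    path: str | Path,
    contexts: Iterable[KymographContext] | dict[str, KymographContext],
) -> list[Track]:
    """Read a vertex table CSV into validated :class:`Track` objects.

    Every ``context_id`` referenced by the table must be defined in
    *contexts*; rows violating track invariants raise ``ValueError`` naming
    the offending track.
    """
    ctx = contexts if isinstance(contexts, dict) else _validate_contexts(contexts)
    df = pd.read_csv(path, dtype={"track_id": str, "context_id": str}, float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table {path} missing columns {missing}")
    tracks: list[Track] = []
    for (tid, cid), grp in df.groupby(["track_id", "context_id"], sort=False):
        if cid not in ctx:
            raise ValueError(f"track {tid!r} references undefined context {cid!r}")
        verts = tuple(TrackVertex(t=float(r.t_s), x=float(r.x_nm)) for r in grp.itertuples())
        tracks.append(Track(track_id=str(tid), vertices=verts, context_id=str(cid)))
    return tracks


def write_tracks(tracks: Iterable[Track], path: str | Path) -> Path:
    """Write tracks to a vertex-table CSV losslessly (full float precision)."""
    rows = [
        (tr.track_id, tr.context_id, repr(v.t), repr(v.x))
        for tr in tracks
        for v in tr.vertices
    ]
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_contexts(path: str | Path) -> dict[str, KymographContext]:
    df = pd.read_csv(path, dtype={"context_id": str, "polarity": str}, float_precision="round_trip")
    missing = [c for c in CONTEXT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"context table {path} missing columns {missing}")
    return _validate_contexts(
        KymographContext(
            context_id=str(r.context_id),
            mt_length_nm=float(r.mt_length_nm),
            duration_s=float(r.duration_s),
            pixel_size_nm=float(r.pixel_size_nm),
            frame_interval_s=float(r.frame_interval_s),
            polarity=str(r.polarity),
        )
        for r in df.itertuples()
    )


def write_contexts(contexts: Iterable[KymographContext] | dict[str, KymographContext], path: str | Path) -> Path:
    vals = contexts.values() if isinstance(contexts, dict) else contexts
    df = pd.DataFrame(
        [
            (c.context_id, repr(c.mt_length_nm), repr(c.duration_s), repr(c.pixel_size_nm), repr(c.frame_interval_s), c.polarity)
            for c in vals
        ],
        columns=CONTEXT_COLUMNS,
    )
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> ExperimentManifest:
    df = pd.read_csv(path, dtype=str)
    return ExperimentManifest(df)


def write_manifest(manifest: ExperimentManifest, path: str | Path) -> Path:
    path = Path(path)
    manifest.table.to_csv(path, index=False)
    return path


def orient_track(track: Track, context: KymographContext) -> Track:
    """Return the track in plus-end-positive coordinates.

    ``plus_right`` traces are already oriented; ``plus_left`` traces have
    every position negated.  An ``unknown`` polarity is a hard error: the
    caller must supply the orientation from the experiment's polarity check.
    """
    if context.polarity == "unknown":
        raise ValueError(
            f"context {context.context_id!r} has unknown polarity; "
            "supply 'plus_right' or 'plus_left' from the polarity-check movie"
        )
    if context.polarity == "plus_right":
        return track
    flipped = tuple(replace(v, x=-v.x) for v in track.vertices)
    return replace(track, vertices=flipped)
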