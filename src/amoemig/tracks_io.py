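"""Reading, validating, filtering and writing cell-trajectory tables.

The on-disk dialect is the ``Spots`` CSV export of common particle-tracking
tools: one row per detection with a track label, a frame index, physical
coordinates in micrometres, a time stamp in seconds and a unitless detection
quality.  Some exporters emit extra non-numeric header-continuation rows
directly after the header; those are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Spot",
    "Track",
    "TrackSet",
    "AcquisitionInfo",
    "FilterReport",
    "DEFAULT_DIALECT",
    "read_spots_table",
    "write_tracks_table",
    "filter_complete",
]

#: Logical field -> column name in the default spots-table dialect.
DEFAULT_DIALECT: dict[str, str] = {
    "track_id": "TRACK_ID",
    "frame": "FRAME",
    "x": "POSITION_X",
    "y": "POSITION_Y",
    "t": "POSITION_T",
    "quality": "QUALITY",
}

_REQUIRED = ("track_id", "frame", "x", "y")


class FormatError(ValueError):
    """A table does not conform to the expected spots dialect."""


class ValidationError(ValueError):
    """A table parses but violates a trajectory invariant."""


@dataclass(frozen=True)
class Spot:
    """One detection: a cell nucleus at one timepoint.

    Coordinates are physical micrometres with the origin at the image
    upper-left corner and y increasing downward; ``frame`` is 0-based and
    ``t`` is seconds from the start of acquisition.
    """

    track_id: int
    frame: int
    t: float
    x: float
    y: float
    quality: float = 0.0

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValidationError(f"negative frame index: {self.frame}")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValidationError(
                f"non-finite coordinates ({self.x}, {self.y}) "
                f"in track {self.track_id} frame {self.frame}"
            )


@dataclass
class Track:
    """A time-ordered trajectory of one cell."""

    track_id: int
    spots: list[Spot]

    def __post_init__(self) -> None:
        frames = [s.frame for s in self.spots]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            if len(set(frames)) != len(frames):
                raise ValidationError(
                    f"duplicate frame in track {self.track_id}"
                )
            raise ValidationError(
                f"spots of track {self.track_id} not ordered by frame"
            )

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots], dtype=int)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.spots], dtype=float)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) in micrometres."""
        return np.array([(s.x, s.y) for s in self.spots], dtype=float)

    def is_complete(self, expected_frames: int) -> bool:
        """True when the track covers frames 0..expected_frames-1 gap-free."""
        f = self.frames
        return len(f) == expected_frames and np.array_equal(
            f, np.arange(expected_frames)
        )


@dataclass(frozen=True)
class AcquisitionInfo:
    """Timing and spatial calibration of a tracking experiment.

    Defaults describe 10 min of imaging at 1 frame / 10 s (60 frames), so
    the final frame of a complete track is at t = 590 s.
    """

    frame_interval: float = 10.0
    n_frames: int = 60
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be positive")
        if self.n_frames < 2:
            raise ValidationError("n_frames must be at least 2")

    @property
    def final_time(self) -> float:
        """Time of the last frame (frame 0 is at t = 0)."""
        return (self.n_frames - 1) * self.frame_interval


@dataclass
class TrackSet:
    """A collection of tracks sharing one acquisition."""

    tracks: list[Track]
    acquisition: AcquisitionInfo = field(default_factory=AcquisitionInfo)

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate track_id in TrackSet")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterable[Track]:
        return iter(self.tracks)

    def by_id(self, track_id: int) -> Track:
        for tr in self.tracks:
            if tr.track_id == track_id:
                return tr
        raise KeyError(track_id)


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_kept: int
    n_dropped: int


def read_spots_table(
    source: str | IO[str],
    dialect: Mapping[str, str] | None = None,
    acquisition: AcquisitionInfo | None = None,
) -> TrackSet:
    """Parse a spots CSV into a :class:`TrackSet`.

    Parameters
    ----------
    source
        Path or open text stream of a comma-separated table with a header.
    dialect
        Logical-field -> column-name overrides, merged over
        :data:`DEFAULT_DIALECT`.
    acquisition
        Timing metadata attached to the result; inferred frame interval is
        not attempted.

    Raises
    ------
    FormatError
        When a required column is missing.
    ValidationError
        When one track holds two spots in the same frame.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(source, dtype=str)
    for logical in _REQUIRED:
        if cols[logical] not in df.columns:
            raise FormatError(f"missing column: {logical}")

    # Export quirk: extra header rows carry non-numeric track ids.
    tid = pd.to_numeric(df[cols["track_id"]], errors="coerce")
    df = df.loc[tid.notna()].copy()
    df["_tid"] = tid.loc[df.index].astype(int)

    def _col(logical: str, default: float | None = None) -> pd.Series:
        name = cols[logical]
        if name in df.columns:
            return pd.to_numeric(df[name], errors="coerce")
        return pd.Series(default, index=df.index, dtype=float)

    frame = _col("frame")
    x, y = _col("x"), _col("y")
    quality = _col("quality", 0.0).fillna(0.0)
    acq = acquisition or AcquisitionInfo()
    t = _col("t")
    t = t.fillna(frame * acq.frame_interval)

    tracks: list[Track] = []
    order = np.lexsort((frame.to_numpy(), df["_tid"].to_numpy()))
    df_s = df.iloc[order]
    for track_id, grp in df_s.groupby("_tid", sort=True):
        idx = grp.index
        fr = frame.loc[idx].astype(int)
        if fr.duplicated().any():
            dup = int(fr[fr.duplicated()].iloc[0])
            raise ValidationError(
                f"duplicate (track, frame) pair: track {track_id} frame {dup}"
            )
        spots = [
            Spot(
                track_id=int(track_id),
                frame=int(fr.loc[i]),
                t=float(t.loc[i]),
                x=float(x.loc[i]),
                y=float(y.loc[i]),
                quality=float(quality.loc[i]),
            )
            for i in idx
        ]
        tracks.append(Track(int(track_id), spots))
    return TrackSet(tracks, acq)


def write_tracks_table(
    ts: TrackSet,
    sink: str | IO[str],
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write a spots CSV readable by :func:`read_spots_table`.

    Coordinates survive a round trip to at least 6 decimal places.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    rows = [
        {
            cols["track_id"]: s.track_id,
            cols["frame"]: s.frame,
            cols["t"]: s.t,
            cols["x"]: s.x,
            cols["y"]: s.y,
            cols["quality"]: s.quality,
        }
        for tr in ts
        for s in tr.spots
    ]
    header = [cols[k] for k in ("track_id", "frame", "x", "y", "t", "quality")]
    pd.DataFrame(rows, columns=header).to_csv(sink, index=False, float_format="%.9g")


def filter_complete(
    ts: TrackSet, expected_frames: int | None = None
) -> tuple[TrackSet, FilterReport]:
    """Keep only tracks covering every frame 0..expected_frames-1.

    Incomplete trajectories (late appearance, early loss, or unclosed gaps)
    are removed so every retained track supports the full battery of
    migration statistics over the same time window.  Idempotent.
    """
    if expected_frames is None:
        expected_frames = ts.acquisition.n_frames
    if expected_frames < 2:
        raise ValidationError("expected_frames must be at least 2")
    kept = [tr for tr in ts if tr.is_complete(expected_frames)]
    report = FilterReport(
        n_input=len(ts), n_kept=len(kept), n_dropped=len(ts) - len(kept)
    )
    return TrackSet(kept, ts.acquisition), report
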