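"""Per-track migration statistics and population curves.

Implements the scalar descriptors of a confined-migration trajectory —
total path length ``D``, net displacement ``d``, confinement ratio
``CR = d / D``, maximum distance traveled, median instantaneous speed —
together with the two population curves: the directionality-ratio (CR
decay) curve over time and the time-averaged mean square displacement
(MSD) over lag.

A trajectory that never moves has an undefined confinement ratio (0/0);
such values are carried as NaN and dropped from aggregation rather than
forced to a number.

Nonmotile cells with strong protrusive activity jiggle their nucleus
around a fixed spot: the path length and speed of such tracks are large
while the maximum distance stays bounded, so path-length-derived
statistics overstate their motility.  Maximum distance and MSD are the
robust descriptors; both are provided here so the dissociation itself
can be quantified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .tracks_io import Track, TrackSet, ValidationError

__all__ = [
    "TrackMetrics",
    "TimeCurve",
    "LagCurve",
    "AggregatedCurve",
    "path_length",
    "displacement",
    "confinement_ratio",
    "max_distance_traveled",
    "median_speed",
    "directionality_ratio_curve",
    "track_msd",
    "aggregate_curves",
    "metrics_table",
]


class InsufficientDataError(ValueError):
    """Track too short for the requested statistic."""


def _check(tr: Track, min_spots: int = 2) -> np.ndarray:
    if len(tr) < min_spots:
        raise InsufficientDataError(
            f"track {tr.track_id} has {len(tr)} spots; need >= {min_spots}"
        )
    return tr.positions


@dataclass(frozen=True)
class TrackMetrics:
    """Scalar migration statistics of one track.

    ``confinement_ratio`` is NaN for a perfectly stationary track.
    """

    track_id: int
    path_length_D: float
    displacement_d: float
    confinement_ratio_CR: float
    max_distance: float
    median_speed: float
    n_frames: int


@dataclass(frozen=True)
class TimeCurve:
    """Directionality ratio per timepoint (frame 1 onward); NaN = undefined."""

    times: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class LagCurve:
    """Time-averaged MSD per lag; lag 0 (MSD = 0) is not stored."""

    lags: np.ndarray
    msd: np.ndarray


@dataclass(frozen=True)
class AggregatedCurve:
    """Mean +/- SD across replicate-level curves on a shared abscissa."""

    abscissa: np.ndarray
    mean_of_replicates: np.ndarray
    sd_of_replicates: np.ndarray
    n_replicates: int


def _step_lengths(p: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(p, axis=0), axis=1)


def path_length(tr: Track) -> float:
    """Total distance traveled: the summed length of all steps, in um."""
    return float(_step_lengths(_check(tr)).sum())


def displacement(tr: Track) -> float:
    """Net displacement: straight-line first-to-last distance, in um."""
    p = _check(tr)
    return float(np.linalg.norm(p[-1] - p[0]))


def confinement_ratio(tr: Track) -> float:
    """CR = d / D in [0, 1]; NaN when the track is perfectly stationary."""
    D = path_length(tr)
    if D == 0.0:
        return float("nan")
    return displacement(tr) / D


def max_distance_traveled(
    tr: Track, mode: Literal["all_pairs", "from_origin"] = "all_pairs"
) -> float:
    """Maximum distance traveled, in um.

    ``all_pairs`` (default): the largest distance between any two
    positions of the track, i.e. the diameter of the visited point set.
    ``from_origin``: the largest distance from the starting position,
    matching the homonymous feature of common tracking tools.
    """
    p = _check(tr)
    if mode == "all_pairs":
        return float(pdist(p).max())
    if mode == "from_origin":
        return float(np.linalg.norm(p - p[0], axis=1).max())
    raise ValueError(f"unknown mode: {mode!r}")


def median_speed(tr: Track) -> float:
    """Median per-step instantaneous speed, in um/s.

    Requires a uniform frame interval; speed of step k is
    ``|p_{k+1} - p_k| / frame_interval``.
    """
    p = _check(tr)
    t = tr.times
    dt = np.diff(t)
    if not np.allclose(dt, dt[0]):
        raise ValidationError(
            f"track {tr.track_id} has a non-uniform frame interval"
        )
    return float(np.median(_step_lengths(p) / dt[0]))


def directionality_ratio_curve(tr: Track) -> TimeCurve:
    """Directionality ratio d(t) / D(t) for each timepoint t >= 1.

    d(t) is the displacement from the start up to t and D(t) the running
    path length.  Timepoints where D(t) = 0 are NaN (undefined, not 1).
    The value at the final timepoint equals the track's confinement ratio.
    """
    p = _check(tr)
    steps = _step_lengths(p)
    run_D = np.cumsum(steps)
    run_d = np.linalg.norm(p[1:] - p[0], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(run_D > 0, run_d / np.where(run_D > 0, run_D, 1.0), np.nan)
    return TimeCurve(times=tr.times[1:].copy(), values=values)


def track_msd(tr: Track) -> LagCurve:
    """Time-averaged MSD with overlapping intervals.

    MSD(n dt) = mean over i of |p_{i+n} - p_i|^2, for every lag
    n = 1..T-1.  Requires a gap-free track.
    """
    p = _check(tr)
    f = tr.frames
    if not np.array_equal(f, np.arange(f[0], f[0] + len(f))):
        raise ValidationError(f"track {tr.track_id} has frame gaps")
    t = tr.times
    dt = t[1] - t[0]
    T = len(p)
    msd = np.empty(T - 1)
    for n in range(1, T):
        d = p[n:] - p[:-n]
        msd[n - 1] = np.mean(np.einsum("ij,ij->i", d, d))
    return LagCurve(lags=dt * np.arange(1, T), msd=msd)


def aggregate_curves(
    curves_by_replicate: Mapping[str, Sequence[np.ndarray]],
    abscissa: np.ndarray,
    stat: Literal["median", "mean"] = "median",
) -> AggregatedCurve:
    """Two-stage aggregation: per-replicate summary, then mean +/- SD.

    Within each replicate the chosen statistic (median for CR-decay
    curves, mean for MSD curves) is taken across cells at every
    timepoint, ignoring NaN; the replicate summaries are then averaged
    with a sample SD (ddof = 1; 0 for a single replicate).
    """
    if not curves_by_replicate:
        raise ValidationError("no replicates to aggregate")
    abscissa = np.asarray(abscissa, dtype=float)
    reducer = np.nanmedian if stat == "median" else np.nanmean
    per_rep = []
    for rep, curves in curves_by_replicate.items():
        arr = np.asarray(list(curves), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(abscissa):
            raise ValidationError(
                f"replicate {rep!r}: curves do not share the abscissa"
            )
        with np.errstate(invalid="ignore"):
            per_rep.append(reducer(arr, axis=0))
    stacked = np.asarray(per_rep)
    mean = np.nanmean(stacked, axis=0)
    if stacked.shape[0] > 1:
        sd = np.nanstd(stacked, axis=0, ddof=1)
    else:
        sd = np.zeros_like(mean)
    return AggregatedCurve(
        abscissa=abscissa,
        mean_of_replicates=mean,
        sd_of_replicates=sd,
        n_replicates=stacked.shape[0],
    )


def compute_metrics(
    tr: Track, mode: Literal["all_pairs", "from_origin"] = "all_pairs"
) -> TrackMetrics:
    """All five scalar statistics of one track."""
    return TrackMetrics(
        track_id=tr.track_id,
        path_length_D=path_length(tr),
        displacement_d=displacement(tr),
        confinement_ratio_CR=confinement_ratio(tr),
        max_distance=max_distance_traveled(tr, mode=mode),
        median_speed=median_speed(tr),
        n_frames=len(tr),
    )


def metrics_table(
    ts: TrackSet,
    replicate: str | None = None,
    mode: Literal["all_pairs", "from_origin"] = "all_pairs",
) -> pd.DataFrame:
    """One row of scalar metrics per track, ordered by track_id."""
    rows = []
    for tr in sorted(ts.tracks, key=lambda t: t.track_id):
        m = compute_metrics(tr, mode=mode)
        rows.append(
            {
                "track_id": m.track_id,
                "replicate": replicate,
                "path_length_D_um": m.path_length_D,
                "displacement_d_um": m.displacement_d,
                "confinement_ratio": m.confinement_ratio_CR,
                "max_distance_um": m.max_distance,
                "median_speed_um_per_s": m.median_speed,
                "n_frames": m.n_frames,
            }
        )
    columns = [
        "track_id",
        "replicate",
        "path_length_D_um",
        "displacement_d_um",
        "confinement_ratio",
        "max_distance_um",
        "median_speed_um_per_s",
        "n_frames",
    ]
    return pd.DataFrame(rows, columns=columns)
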