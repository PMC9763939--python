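"""Nucleus detection and particle linking for synthetic movies.

Detection uses a scale-normalized Laplacian-of-Gaussian blob detector at
a scale matched to the expected nucleus diameter, with sub-pixel
localization by a local quadratic fit.  Linking solves the
frame-to-frame assignment problem optimally (Hungarian algorithm with a
no-link alternative), and short breaks are repaired by greedy gap
closing.  Quality is defined relative to the brightest detection of the
stack, so the quality threshold is a unitless fraction in (0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_laplace, maximum_filter
from scipy.optimize import linear_sum_assignment

from .tracks_io import AcquisitionInfo, Spot, Track, TrackSet

__all__ = [
    "DetectionParams",
    "LinkingParams",
    "TrackingEvaluation",
    "detect_spots",
    "detect_movie",
    "link_frames",
    "close_gaps",
    "track_movie",
    "evaluate_tracking",
]

_BIG = 1e12


@dataclass(frozen=True)
class DetectionParams:
    """LoG blob-detection settings.

    ``object_diameter`` is the expected nucleus diameter in um (10 by
    default; larger-nucleus lines need 12, primary cells 9).  The LoG
    scale is ``sigma = diameter / (2 sqrt(2))`` converted to pixels.
    """

    object_diameter: float = 10.0
    quality_threshold: float = 0.2
    pixel_size: float = 0.65

    @property
    def sigma_px(self) -> float:
        return self.object_diameter / (2.0 * math.sqrt(2.0)) / self.pixel_size


@dataclass(frozen=True)
class LinkingParams:
    """Frame-to-frame linking and gap-closing radii (um) and max frame gap."""

    linking_max_distance: float = 10.0
    gap_closing_max_distance: float = 15.0
    gap_closing_max_frame_gap: int = 2


@dataclass(frozen=True)
class TrackingEvaluation:
    n_truth_tracks: int
    n_recovered_complete: int
    recovery_fraction: float
    mean_position_error: float


def _log_response(frame: np.ndarray, sigma_px: float) -> np.ndarray:
    # scale-normalized negative LoG: bright blobs -> positive peaks.
    # The DC offset is removed first so kernel-truncation error on a flat
    # background cannot masquerade as signal.
    f = frame.astype(np.float64)
    return -(sigma_px**2) * gaussian_laplace(f - f.mean(), sigma_px)


def _quadratic_offset(fm: float, f0: float, fp: float) -> float:
    denom = fm - 2.0 * f0 + fp
    if denom >= 0:  # not a concave peak; keep integer position
        return 0.0
    return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))


def detect_spots(
    frame: np.ndarray,
    p: DetectionParams,
    frame_index: int = 0,
    t: float | None = None,
    response_norm: float | None = None,
) -> list[Spot]:
    """Detect nucleus candidates in one frame.

    Candidates are local maxima of the negated, scale-normalized LoG
    response; quality is the response divided by ``response_norm`` (the
    brightest response of the movie; defaults to this frame's maximum),
    and candidates below ``quality_threshold`` are discarded.  Positions
    are refined per axis by a three-point parabola and returned in um.
    A constant frame yields no spots.
    """
    resp = _log_response(frame, p.sigma_px)
    # floor against float jitter on flat images: a real blob's response is
    # of the order of the image intensity scale
    eps = 1e-9 * max(float(np.abs(frame).max()), 1.0)
    if response_norm is None:
        response_norm = float(resp.max())
    if response_norm <= eps:
        return []
    is_max = (resp == maximum_filter(resp, size=3)) & (resp > 0)
    is_max[0, :] = is_max[-1, :] = False
    is_max[:, 0] = is_max[:, -1] = False
    spots: list[Spot] = []
    for r, c in zip(*np.nonzero(is_max)):
        quality = resp[r, c] / response_norm
        if quality < p.quality_threshold:
            continue
        dr = _quadratic_offset(resp[r - 1, c], resp[r, c], resp[r + 1, c])
        dc = _quadratic_offset(resp[r, c - 1], resp[r, c], resp[r, c + 1])
        spots.append(
            Spot(
                track_id=-1,
                frame=frame_index,
                t=frame_index * 10.0 if t is None else t,
                x=(c + dc) * p.pixel_size,
                y=(r + dr) * p.pixel_size,
                quality=float(quality),
            )
        )
    return spots


def detect_movie(
    stack: np.ndarray,
    p: DetectionParams,
    frame_interval: float = 10.0,
) -> list[list[Spot]]:
    """Detect spots in every frame, normalizing quality over the stack."""
    responses = [_log_response(fr, p.sigma_px) for fr in stack]
    norm = max(float(r.max()) for r in responses)
    return [
        detect_spots(
            fr, p, frame_index=i, t=i * frame_interval, response_norm=norm
        )
        for i, fr in enumerate(stack)
    ]


def _assignment(
    a: np.ndarray, b: np.ndarray, max_dist: float
) -> list[tuple[int, int]]:
    """Optimal one-to-one links between point sets a and b.

    Minimizes total squared distance over links within ``max_dist``,
    with a no-link alternative priced just above the radius so a link is
    made whenever it is cheaper than leaving both points unmatched.
    """
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        return []
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    cost_nolink = max_dist**2 * 1.05
    tl = np.where(d2 <= max_dist**2, d2, _BIG)
    size = n1 + n2
    C = np.full((size, size), 0.0)
    C[:n1, :n2] = tl
    C[:n1, n2:] = np.where(np.eye(n1, dtype=bool), cost_nolink, _BIG)
    C[n1:, :n2] = np.where(np.eye(n2, dtype=bool), cost_nolink, _BIG)
    rows, cols = linear_sum_assignment(C)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n1 and c < n2 and tl[r, c] < _BIG
    ]


def link_frames(
    spots_per_frame: Sequence[Sequence[Spot]], p: LinkingParams
) -> list[list[Spot]]:
    """Link detections frame to frame into tracklets.

    Each consecutive frame pair is solved as an optimal assignment;
    unmatched detections terminate or start tracklets.  No two spots of
    one frame ever share a successor.
    """
    tracklets: list[list[Spot]] = []
    open_by_index: dict[int, list[Spot]] = {}
    prev: list[Spot] = []
    for spots in spots_per_frame:
        spots = list(spots)
        links = _assignment(
            np.array([(s.x, s.y) for s in prev]).reshape(-1, 2),
            np.array([(s.x, s.y) for s in spots]).reshape(-1, 2),
            p.linking_max_distance,
        )
        next_open: dict[int, list[Spot]] = {}
        matched_curr = set()
        for i, j in links:
            tl = open_by_index[i]
            tl.append(spots[j])
            next_open[j] = tl
            matched_curr.add(j)
        for j, s in enumerate(spots):
            if j not in matched_curr:
                tl = [s]
                tracklets.append(tl)
                next_open[j] = tl
        open_by_index = next_open
        prev = spots
    return tracklets


def close_gaps(
    tracklets: Sequence[list[Spot]],
    p: LinkingParams,
    interpolate: bool = False,
) -> TrackSet:
    """Join tracklets across short breaks; relabel into a TrackSet.

    An end at frame f may join a start at frame f + g for
    ``1 <= g <= gap_closing_max_frame_gap`` when the end-start distance
    is within ``gap_closing_max_distance``; candidates are taken
    greedily by ascending distance, each end and start used once.
    Bridged frames stay absent unless ``interpolate`` fills them
    linearly (off by default, so gap-closed tracks fail a
    complete-track filter).
    """
    tls = [list(t) for t in tracklets]
    candidates = []
    for i, a in enumerate(tls):
        for j, b in enumerate(tls):
            if i == j:
                continue
            gap = b[0].frame - a[-1].frame
            if 1 <= gap <= p.gap_closing_max_frame_gap:
                d = math.hypot(b[0].x - a[-1].x, b[0].y - a[-1].y)
                if d <= p.gap_closing_max_distance:
                    candidates.append((d, i, j))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    succ: dict[int, int] = {}
    used_starts: set[int] = set()
    for d, i, j in candidates:
        if i in succ or j in used_starts:
            continue
        succ[i] = j
        used_starts.add(j)
    # stitch chains starting from tracklets that are not anyone's successor
    tracks: list[Track] = []
    tid = 0
    for i in range(len(tls)):
        if i in used_starts:
            continue
        chain = list(tls[i])
        k = i
        while k in succ:
            k = succ[k]
            if interpolate:
                a, b = chain[-1], tls[k][0]
                for f in range(a.frame + 1, b.frame):
                    w = (f - a.frame) / (b.frame - a.frame)
                    chain.append(
                        Spot(
                            track_id=-1,
                            frame=f,
                            t=a.t + w * (b.t - a.t),
                            x=a.x + w * (b.x - a.x),
                            y=a.y + w * (b.y - a.y),
                            quality=0.0,
                        )
                    )
            chain.extend(tls[k])
        spots = [
            Spot(tid, s.frame, s.t, s.x, s.y, s.quality) for s in chain
        ]
        tracks.append(Track(tid, spots))
        tid += 1
    return TrackSet(tracks)


def track_movie(
    stack: np.ndarray,
    detection: DetectionParams | None = None,
    linking: LinkingParams | None = None,
    frame_interval: float = 10.0,
    interpolate: bool = False,
) -> TrackSet:
    """Full detection + linking + gap closing on an image stack."""
    detection = detection or DetectionParams()
    linking = linking or LinkingParams()
    spots = detect_movie(stack, detection, frame_interval)
    tls = link_frames(spots, linking)
    ts = close_gaps(tls, linking, interpolate=interpolate)
    return TrackSet(
        ts.tracks,
        AcquisitionInfo(
            frame_interval=frame_interval,
            n_frames=len(stack),
            pixel_size=detection.pixel_size,
        ),
    )


def evaluate_tracking(
    computed: TrackSet, truth: TrackSet, tol: float = 1.0
) -> TrackingEvaluation:
    """Fraction of truth tracks recovered spot-for-spot within ``tol`` um.

    A truth track counts as recovered when some computed track covers
    exactly its frames with every position within ``tol``; the mean
    position error is averaged over all matched spots of recovered
    tracks.
    """
    n_rec = 0
    errors: list[float] = []
    for tt in truth:
        t_pos = tt.positions
        t_frames = tt.frames
        best: np.ndarray | None = None
        for ct in computed:
            if not np.array_equal(ct.frames, t_frames):
                continue
            err = np.linalg.norm(ct.positions - t_pos, axis=1)
            if err.max() <= tol and (best is None or err.mean() < best.mean()):
                best = err
        if best is not None:
            n_rec += 1
            errors.extend(best)
    n = len(truth.tracks)
    return TrackingEvaluation(
        n_truth_tracks=n,
        n_recovered_complete=n_rec,
        recovery_fraction=n_rec / n if n else 0.0,
        mean_position_error=float(np.mean(errors)) if errors else 0.0,
    )
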