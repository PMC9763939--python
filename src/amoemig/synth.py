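"""Synthetic trajectories and microscopy images for the pipeline.

Two motility phenotypes are modelled, matching what confined leukemic
B cells do under agarose:

* a **persistent random walk** (migratory phenotype): the velocity is a
  2-D Ornstein-Uhlenbeck process with correlation time ``P``, so the
  ensemble MSD follows the Fürth form
  ``MSD(t) = 4 D_c [t - P (1 - exp(-t/P))]`` with ``D_c = sigma_v^2 P``;
* an **anchored oscillator** (nonmotile phenotype): the nucleus position
  is a mean-reverting (AR(1)) jitter around a fixed anchor with
  stationary per-axis SD ``a`` and a large per-frame step, reproducing
  the protrusion-driven nucleus jiggle that inflates track length and
  speed without net movement.

Renderers turn ground-truth geometry into noisy 16-bit images: nucleus
movies (Gaussian blobs per frame, for the tracking stage) and
single-cell membrane-stain stills with punctate vesicle signal either
dispersed through the cytoplasm or clustered in a polar uropod cap (for
the dispersion-scoring stage).  Every generator is a pure function of
its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .tracks_io import AcquisitionInfo, Spot, Track, TrackSet

__all__ = [
    "PRWParams",
    "OscillatoryParams",
    "RenderParams",
    "VesicleSceneParams",
    "PRESETS",
    "simulate_prw_track",
    "simulate_oscillatory_track",
    "simulate_ballistic_track",
    "simulate_ensemble",
    "render_movie",
    "render_vesicle_cell",
]


@dataclass(frozen=True)
class PRWParams:
    """Persistent-random-walk parameters.

    ``mean_speed`` is the stationary mean speed (um/s) of the OU
    velocity process; the per-axis velocity SD is derived from it
    (``sigma_v = mean_speed * sqrt(2/pi)`` for a 2-D isotropic Gaussian
    velocity) unless ``speed_sd`` overrides it directly.
    """

    mean_speed: float = 0.1
    persistence_time_P: float = 60.0
    speed_sd: float | None = None
    n_frames: int = 60
    frame_interval: float = 10.0
    seed: int = 0

    @property
    def sigma_v(self) -> float:
        if self.speed_sd is not None:
            return self.speed_sd
        return self.mean_speed * math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class OscillatoryParams:
    """Anchored-oscillator parameters.

    ``anchor_sd_a`` is the stationary per-axis SD (um) of the position
    around the anchor; ``step_scale`` the mean per-frame step length
    (um).  The AR(1) coefficient follows from the two:
    ``rho = 1 - s^2 / (2 a^2)`` with ``s = step_scale * sqrt(2/pi)``
    the per-axis step SD, and is negative (anti-persistent) at the
    defaults — the nucleus overshoots back and forth across the anchor.
    """

    anchor_sd_a: float = 1.0
    step_scale: float = 2.0
    n_frames: int = 60
    frame_interval: float = 10.0
    seed: int = 0

    @property
    def rho(self) -> float:
        s2 = (self.step_scale * math.sqrt(2.0 / math.pi)) ** 2
        rho = 1.0 - s2 / (2.0 * self.anchor_sd_a**2)
        if not -1.0 < rho < 1.0:
            raise ValueError(
                "step_scale too large for anchor_sd_a: process not stationary"
            )
        return rho


@dataclass(frozen=True)
class RenderParams:
    """Nucleus-movie rendering: geometry in px, intensities in 16-bit units."""

    image_size: int = 512
    pixel_size: float = 0.65
    nucleus_sigma: float = 5.4
    peak_intensity: float = 8000.0
    background: float = 400.0
    noise_sd: float = 60.0
    seed: int = 0


@dataclass(frozen=True)
class VesicleSceneParams:
    """Single-cell membrane-stain scene with punctate vesicles."""

    cell_radius: float = 8.0
    n_vesicles: int = 25
    mode: Literal["polarized", "dispersed"] = "dispersed"
    cap_fraction: float = 0.2
    vesicle_sigma: float = 1.5
    vesicle_peak: float = 3000.0
    cell_intensity: float = 120.0
    background: float = 200.0
    noise_sd: float = 30.0
    image_size: int = 160
    pixel_size: float = 0.1626
    axis_ratio: float = 1.3
    seed: int = 0


#: Named phenotype presets; metric ranges are qualitative calibration only.
PRESETS: dict[str, PRWParams | OscillatoryParams] = {
    "migratory-CLL-like": PRWParams(),
    "oscillatory-MCL-like": OscillatoryParams(),
}


def _track_from_xy(
    xy: np.ndarray, frame_interval: float, track_id: int
) -> Track:
    spots = [
        Spot(
            track_id=track_id,
            frame=i,
            t=i * frame_interval,
            x=float(x),
            y=float(y),
        )
        for i, (x, y) in enumerate(xy)
    ]
    return Track(track_id, spots)


def simulate_prw_track(
    p: PRWParams,
    start: tuple[float, float] = (0.0, 0.0),
    track_id: int = 0,
    rng: np.random.Generator | None = None,
) -> Track:
    """Simulate one persistent-random-walk track.

    The velocity is a stationary OU process with correlation time
    ``P``; positions are its exact time integral, sampled jointly with
    the velocity at each frame (the displacement over a frame and the
    end-of-frame velocity are correlated Gaussians with the analytic
    integrated-OU covariance).  The ensemble MSD therefore equals the
    Fürth form ``4 sigma_v^2 P [t - P (1 - e^(-t/P))]`` exactly at the
    sample times, with no discretization bias.
    """
    rng = rng or np.random.default_rng(p.seed)
    P = p.persistence_time_P
    dt = p.frame_interval
    r = math.exp(-dt / P)
    sv2 = p.sigma_v**2
    # conditional (on v_k) covariance of (displacement, v_{k+1}) per axis
    var_p = sv2 * (2.0 * P * dt - P * P * (1.0 - r) * (3.0 - r))
    var_v = sv2 * (1.0 - r * r)
    cov_pv = sv2 * P * (1.0 - r) ** 2
    sp = math.sqrt(var_p)
    c1 = cov_pv / sp
    c2 = math.sqrt(max(var_v - c1 * c1, 0.0))
    v = rng.normal(0.0, math.sqrt(sv2), size=2)  # stationary start
    xy = np.empty((p.n_frames, 2))
    xy[0] = start
    z = rng.standard_normal(size=(p.n_frames - 1, 2, 2))
    for k in range(1, p.n_frames):
        z1, z2 = z[k - 1]
        dp = v * P * (1.0 - r) + sp * z1
        xy[k] = xy[k - 1] + dp
        v = v * r + c1 * z1 + c2 * z2
    return _track_from_xy(xy, p.frame_interval, track_id)


def simulate_oscillatory_track(
    p: OscillatoryParams,
    anchor: tuple[float, float] = (0.0, 0.0),
    track_id: int = 0,
    rng: np.random.Generator | None = None,
) -> Track:
    """Simulate one anchored-oscillator track (stationary AR(1) jitter)."""
    rng = rng or np.random.default_rng(p.seed)
    rho = p.rho
    a = p.anchor_sd_a
    innov_sd = a * math.sqrt(1.0 - rho * rho)
    x = rng.normal(0.0, a, size=2)  # stationary start
    xy = np.empty((p.n_frames, 2))
    for k in range(p.n_frames):
        xy[k] = np.asarray(anchor) + x
        if k < p.n_frames - 1:
            x = x * rho + rng.normal(0.0, innov_sd, size=2)
    return _track_from_xy(xy, p.frame_interval, track_id)


def simulate_ballistic_track(
    speed: float,
    direction: float = 0.0,
    n_frames: int = 60,
    frame_interval: float = 10.0,
    start: tuple[float, float] = (0.0, 0.0),
    track_id: int = 0,
) -> Track:
    """Straight constant-velocity track: ``p_t = p_0 + v t`` exactly."""
    if speed < 0:
        raise ValueError("speed must be non-negative")
    v = speed * np.array([math.cos(direction), math.sin(direction)])
    t = frame_interval * np.arange(n_frames)
    xy = np.asarray(start) + np.outer(t, v)
    return _track_from_xy(xy, frame_interval, track_id)


def simulate_ensemble(
    params: PRWParams | OscillatoryParams,
    n_tracks: int,
    seed: int | None = None,
) -> TrackSet:
    """Independent tracks from one parameter set, seeded reproducibly."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    tracks = []
    for i in range(n_tracks):
        if isinstance(params, PRWParams):
            tracks.append(simulate_prw_track(params, track_id=i, rng=rng))
        else:
            tracks.append(simulate_oscillatory_track(params, track_id=i, rng=rng))
    acq = AcquisitionInfo(
        frame_interval=params.frame_interval, n_frames=params.n_frames
    )
    return TrackSet(tracks, acq)


def _add_gaussian_blob(
    img: np.ndarray, cx: float, cy: float, sigma: float, peak: float
) -> None:
    """Add a 2-D Gaussian at (col=cx, row=cy), rendered on a local patch."""
    h, w = img.shape
    half = int(math.ceil(4 * sigma))
    r0 = max(int(round(cy)) - half, 0)
    r1 = min(int(round(cy)) + half + 1, h)
    c0 = max(int(round(cx)) - half, 0)
    c1 = min(int(round(cx)) + half + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    img[r0:r1, c0:c1] += peak * np.exp(
        -((cc - cx) ** 2 + (rr - cy) ** 2) / (2 * sigma**2)
    )


def render_movie(
    truth: TrackSet, p: RenderParams
) -> tuple[np.ndarray, TrackSet]:
    """Render a nucleus movie from ground-truth tracks.

    Each nucleus is a 2-D Gaussian at its true position on a constant
    background with additive Gaussian noise, saturated to 16-bit.
    Returns ``(stack, truth)`` with ``stack`` of shape
    (n_frames, image_size, image_size), dtype uint16.
    """
    rng = np.random.default_rng(p.seed)
    n_frames = truth.acquisition.n_frames
    extent = p.image_size * p.pixel_size
    for tr in truth:
        pos = tr.positions
        if pos.min() < 0 or pos.max() >= extent:
            raise ValueError(
                f"track {tr.track_id} leaves the field (0..{extent:.1f} um)"
            )
    stack = np.zeros((n_frames, p.image_size, p.image_size), dtype=np.float64)
    for tr in truth:
        for s in tr.spots:
            _add_gaussian_blob(
                stack[s.frame],
                s.x / p.pixel_size,
                s.y / p.pixel_size,
                p.nucleus_sigma,
                p.peak_intensity,
            )
    stack += p.background
    stack += rng.normal(0.0, p.noise_sd, size=stack.shape)
    return np.clip(stack, 0, 65535).astype(np.uint16), truth


def _cap_chord(cap_fraction: float) -> float:
    """u in (-1, 1) such that the unit-disk area with x > u is cap_fraction."""
    f = lambda u: (math.acos(u) - u * math.sqrt(1 - u * u)) / math.pi - cap_fraction
    return brentq(f, -0.999999, 0.999999)


def render_vesicle_cell(
    p: VesicleSceneParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one membrane-stained cell with punctate vesicle signal.

    The cell body is an ellipse of diffuse intensity (soft edge);
    vesicles are Gaussian puncta placed uniformly over the cytoplasm
    (``dispersed``) or uniformly over a polar cap holding
    ``cap_fraction`` of the cell area at the +x pole (``polarized``),
    emulating uropod accumulation.  Returns ``(image, truth_um)`` where
    ``truth_um`` is the (n, 2) array of true vesicle (x, y) in um.
    """
    if not 0.0 < p.cap_fraction < 1.0:
        raise ValueError("cap_fraction must be in (0, 1)")
    rng = np.random.default_rng(p.seed)
    n = p.image_size
    ctr = (n - 1) / 2.0
    a_px = p.cell_radius * math.sqrt(p.axis_ratio) / p.pixel_size  # semi-major, x
    b_px = p.cell_radius / math.sqrt(p.axis_ratio) / p.pixel_size  # semi-minor, y
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    inside = ((cc - ctr) / a_px) ** 2 + ((rr - ctr) / b_px) ** 2 <= 1.0
    img = np.full((n, n), p.background, dtype=np.float64)
    # soft-edged cell body
    from scipy.ndimage import gaussian_filter

    img += p.cell_intensity * gaussian_filter(inside.astype(float), 2.0)

    # sample vesicle positions on the unit disk, then map to the ellipse
    pts = []
    u_min = _cap_chord(p.cap_fraction) if p.mode == "polarized" else None
    margin = 0.92  # keep puncta off the membrane edge
    while len(pts) < p.n_vesicles:
        u, v = rng.uniform(-1, 1, size=2)
        if u * u + v * v > 1.0:
            continue
        if u_min is not None and u < u_min:
            continue
        pts.append((u * margin, v * margin))
    truth_px = np.array(
        [(ctr + u * a_px, ctr + v * b_px) for u, v in pts]
    ).reshape(-1, 2)  # (col, row)
    for cx, cy in truth_px:
        _add_gaussian_blob(img, cx, cy, p.vesicle_sigma, p.vesicle_peak)
    img += rng.normal(0.0, p.noise_sd, size=img.shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)
    truth_um = truth_px * p.pixel_size
    return img, truth_um
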