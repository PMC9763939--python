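"""Standard synthetic scenes used by tests, examples and the CLI.

These fix the study conditions the rest of the package is validated
under: a 60-frame, 10-s-interval nucleus movie of 20 well-separated
cells, and cohorts of polarized / dispersed vesicle cells.
"""

from __future__ import annotations

import numpy as np

from .synth import (
    OscillatoryParams,
    PRWParams,
    RenderParams,
    VesicleSceneParams,
    render_movie,
    render_vesicle_cell,
    simulate_oscillatory_track,
    simulate_prw_track,
)
from .tracks_io import AcquisitionInfo, Spot, Track, TrackSet

__all__ = ["default_tracking_movie", "vesicle_cohort"]


def default_tracking_movie(
    n_cells: int = 20,
    seed: int = 0,
    preset: str = "migratory-CLL-like",
    render: RenderParams | None = None,
):
    """A nucleus movie of well-separated cells with ground truth.

    Cells start on a jittered grid with enough margin that a
    persistent walker stays inside the field for the full hour of
    frames; rendering uses defaults giving SNR well above 5
    (peak/noise ~ 130).  Returns ``(stack, truth_trackset)``.
    """
    render = render or RenderParams(seed=seed)
    rng = np.random.default_rng(seed)
    extent = render.image_size * render.pixel_size
    margin = 0.25 * extent
    side = int(np.ceil(np.sqrt(n_cells)))
    xs = np.linspace(margin, extent - margin, side)
    starts = [(x, y) for y in xs for x in xs][:n_cells]
    tracks = []
    for i, (x0, y0) in enumerate(starts):
        jitter = rng.uniform(-2, 2, size=2)
        if preset == "migratory-CLL-like":
            tr = simulate_prw_track(
                PRWParams(), start=(x0 + jitter[0], y0 + jitter[1]),
                track_id=i, rng=rng,
            )
        else:
            tr = simulate_oscillatory_track(
                OscillatoryParams(), anchor=(x0 + jitter[0], y0 + jitter[1]),
                track_id=i, rng=rng,
            )
        tracks.append(tr)
    truth = TrackSet(tracks, AcquisitionInfo(10.0, 60, render.pixel_size))
    stack, _ = render_movie(truth, render)
    return stack, truth


def vesicle_cohort(
    mode: str,
    n_cells: int = 50,
    n_replicates: int = 5,
    seed: int = 0,
    **scene_kwargs,
):
    """A cohort of single-cell vesicle crops split into replicates.

    Returns a list of ``(cell_id, replicate, image, truth_um)`` tuples;
    replicate labels cycle so each of the ``n_replicates`` batches gets
    ``n_cells / n_replicates`` cells.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_cells):
        p = VesicleSceneParams(
            mode=mode, seed=int(rng.integers(2**31)), **scene_kwargs
        )
        img, truth = render_vesicle_cell(p)
        rep = f"rep{i % n_replicates}"
        out.append((f"{mode}_{i}", rep, img, truth))
    return out
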