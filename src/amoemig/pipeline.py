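"""End-to-end orchestration: movies or spot tables -> metrics -> statistics.

A run is driven by a single YAML config describing the experiment layout
(condition -> replicate -> input path) plus parameter blocks for each
stage; results are written as CSV bundles.  CSVs are the contract;
every table round-trips through the corresponding reader.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .metrics import (
    aggregate_curves,
    directionality_ratio_curve,
    metrics_table,
    track_msd,
)
from .stats import grouped_values_from_long, superplot_summary
from .tracking import DetectionParams, LinkingParams, track_movie
from .tracks_io import AcquisitionInfo, TrackSet, filter_complete, read_spots_table
from .vesicles import GridParams, MaximaParams, batch_score

log = logging.getLogger("amoemig")

__all__ = ["RunConfig", "run_migration_analysis", "run_vesicle_analysis"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration.

    ``layout`` maps condition -> replicate -> input path (spots CSV or
    TIFF movie for migration runs; single-cell crop TIFF/stack for
    vesicle runs).
    """

    layout: dict[str, dict[str, str]]
    out_dir: str = "results"
    seed: int = 0
    frame_interval_s: float = 10.0
    expected_frames: int = 60
    pixel_size_um: float = 0.65
    detection: DetectionParams = field(default_factory=DetectionParams)
    linking: LinkingParams = field(default_factory=LinkingParams)
    grid: GridParams = field(default_factory=GridParams)
    maxima: MaximaParams = field(default_factory=MaximaParams)
    vesicle_pixel_size_um: float = 0.1626
    max_distance_mode: str = "all_pairs"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {"layout": raw.get("layout", {})}
        for key in (
            "out_dir", "seed", "frame_interval_s", "expected_frames",
            "pixel_size_um", "vesicle_pixel_size_um", "max_distance_mode",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        for key, klass in (
            ("detection", DetectionParams),
            ("linking", LinkingParams),
            ("grid", GridParams),
            ("maxima", MaximaParams),
        ):
            if key in raw:
                kwargs[key] = klass(**raw[key])
        return cls(**kwargs)

    def digest(self) -> str:
        payload = {
            "layout": self.layout,
            "seed": self.seed,
            "frame_interval_s": self.frame_interval_s,
            "expected_frames": self.expected_frames,
            "detection": asdict(self.detection),
            "linking": asdict(self.linking),
            "grid": asdict(self.grid),
            "maxima": asdict(self.maxima),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_trackset(path: str | Path, cfg: RunConfig) -> TrackSet:
    path = Path(path)
    acq = AcquisitionInfo(
        frame_interval=cfg.frame_interval_s,
        n_frames=cfg.expected_frames,
        pixel_size=cfg.pixel_size_um,
    )
    if path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        return track_movie(
            stack, cfg.detection, cfg.linking, frame_interval=cfg.frame_interval_s
        )
    return read_spots_table(str(path), acquisition=acq)


def _provenance(cfg: RunConfig) -> dict[str, Any]:
    return {"version": __version__, "config_hash": cfg.digest(), "seed": cfg.seed}


def run_migration_analysis(cfg: RunConfig) -> dict[str, Path]:
    """Movies/spot tables -> per-track metrics, curves and SuperPlot stats.

    Emits four CSV artifacts into ``cfg.out_dir``: ``track_metrics.csv``,
    ``cr_decay.csv``, ``msd.csv`` and ``superplot_summary.csv``, plus a
    JSON provenance log including dropped-track counts.  Raises when a
    replicate retains zero complete tracks.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_metrics: list[pd.DataFrame] = []
    cr_rows, msd_rows = [], []
    drop_log: dict[str, dict[str, int]] = {}
    cr_by_cond: dict[str, dict[str, list[np.ndarray]]] = {}
    msd_by_cond: dict[str, dict[str, list[np.ndarray]]] = {}
    abscissa_t = cfg.frame_interval_s * np.arange(1, cfg.expected_frames)

    for cond, reps in cfg.layout.items():
        for rep, path in reps.items():
            ts = _load_trackset(path, cfg)
            ts, report = filter_complete(ts, cfg.expected_frames)
            drop_log.setdefault(cond, {})[rep] = report.n_dropped
            if len(ts) == 0:
                raise PipelineError(
                    f"zero complete tracks in condition {cond!r} replicate {rep!r}"
                )
            mt = metrics_table(ts, replicate=rep, mode=cfg.max_distance_mode)
            mt.insert(0, "condition", cond)
            all_metrics.append(mt)
            for tr in ts:
                cr = directionality_ratio_curve(tr).values
                msd = track_msd(tr).msd
                cr_by_cond.setdefault(cond, {}).setdefault(rep, []).append(cr)
                msd_by_cond.setdefault(cond, {}).setdefault(rep, []).append(msd)

    metrics_df = pd.concat(all_metrics, ignore_index=True)
    for cond in cr_by_cond:
        agg_cr = aggregate_curves(cr_by_cond[cond], abscissa_t, stat="median")
        agg_msd = aggregate_curves(msd_by_cond[cond], abscissa_t, stat="mean")
        for t, m, s in zip(abscissa_t, agg_cr.mean_of_replicates,
                           agg_cr.sd_of_replicates):
            cr_rows.append({"condition": cond, "time_s": t, "mean": m, "sd": s,
                            "n_replicates": agg_cr.n_replicates})
        for t, m, s in zip(abscissa_t, agg_msd.mean_of_replicates,
                           agg_msd.sd_of_replicates):
            msd_rows.append({"condition": cond, "lag_s": t, "mean_um2": m,
                             "sd_um2": s, "n_replicates": agg_msd.n_replicates})

    long = metrics_df.rename(columns={"max_distance_um": "value"})[
        ["condition", "replicate", "value"]
    ]
    summary = superplot_summary(grouped_values_from_long(long))
    sum_df = summary.to_frame()
    sum_df["anova_F"] = summary.anova_F
    sum_df["anova_p"] = summary.anova_p

    paths = {
        "track_metrics": out / "track_metrics.csv",
        "cr_decay": out / "cr_decay.csv",
        "msd": out / "msd.csv",
        "superplot_summary": out / "superplot_summary.csv",
    }
    metrics_df.to_csv(paths["track_metrics"], index=False, float_format="%.9g")
    pd.DataFrame(cr_rows).to_csv(paths["cr_decay"], index=False, float_format="%.9g")
    pd.DataFrame(msd_rows).to_csv(paths["msd"], index=False, float_format="%.9g")
    sum_df.to_csv(paths["superplot_summary"], index=False, float_format="%.9g")
    with open(out / "run_log.json", "w") as fh:
        json.dump({**_provenance(cfg), "dropped_tracks": drop_log}, fh, indent=2)
    paths["run_log"] = out / "run_log.json"
    return paths


def run_vesicle_analysis(
    cfg: RunConfig, methods: tuple[str, ...] = ("grid", "maxima")
) -> dict[str, Path]:
    """Single-cell crops -> dispersion scores per method + SuperPlot stats."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    exclusions = []
    for method in methods:
        frames = []
        for cond, reps in cfg.layout.items():
            for rep, path in reps.items():
                stack = tifffile.imread(path)
                if stack.ndim == 2:
                    stack = stack[None]
                crops = [(f"{cond}/{rep}/{i}", im) for i, im in enumerate(stack)]
                scores = batch_score(
                    crops, cfg.vesicle_pixel_size_um, method=method,
                    grid_params=cfg.grid, maxima_params=cfg.maxima,
                )
                scores.insert(0, "condition", cond)
                scores.insert(1, "replicate", rep)
                frames.append(scores)
        table = pd.concat(frames, ignore_index=True)
        exclusions.append(table[table["status"] != "ok"])
        ok = table[table["status"] == "ok"]
        if ok.empty:
            raise PipelineError(f"all cells excluded for method {method!r}")
        score_path = out / f"dispersion_{method}.csv"
        table.to_csv(score_path, index=False, float_format="%.9g")
        paths[f"scores_{method}"] = score_path
        long = ok.rename(columns={"score_um": "value"})[
            ["condition", "replicate", "value"]
        ]
        gv = grouped_values_from_long(long)
        summary = superplot_summary(gv)
        sum_df = summary.to_frame()
        sum_df["anova_F"] = summary.anova_F
        sum_df["anova_p"] = summary.anova_p
        sum_path = out / f"dispersion_{method}_summary.csv"
        sum_df.to_csv(sum_path, index=False, float_format="%.9g")
        paths[f"summary_{method}"] = sum_path
    excl = pd.concat(exclusions, ignore_index=True)
    excl.to_csv(out / "exclusions.csv", index=False)
    paths["exclusions"] = out / "exclusions.csv"
    with open(out / "run_log.json", "w") as fh:
        json.dump(_provenance(cfg), fh, indent=2)
    paths["run_log"] = out / "run_log.json"
    return paths
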