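"""Vesicle-dispersion scoring of single-cell membrane-stain images.

Polarized migrating lymphocytes concentrate endocytic vesicles in the
uropod; depolarized cells scatter them through the cytoplasm.  Both
scoring procedures implemented here reduce a single-cell image to the
per-cell **median of all mutual distances** between detected vesicle
loci (um) — small when the signal is clustered at one pole, large when
dispersed:

* the **grid** method tiles the segmented cell into small squares,
  takes each square's median intensity, and keeps squares above a
  per-cell relative threshold (a multiple of the dimmest square);
  positive-square centroids are the loci;
* the **maxima** method finds intensity maxima of topographic
  prominence above a cutoff inside the cell mask; the maxima are the
  loci.

Segmentation follows contrast stretch -> Gaussian blur (sigma = 2 px)
-> Huang fuzzy thresholding -> largest connected component; cells
touching the image border are flagged for exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import pdist
from skimage.measure import label

__all__ = [
    "GridParams",
    "MaximaParams",
    "SegmentationResult",
    "DispersionScore",
    "huang_threshold",
    "segment_cell",
    "grid_dispersion_score",
    "find_maxima",
    "maxima_dispersion_score",
    "batch_score",
]


@dataclass(frozen=True)
class GridParams:
    """Grid-method settings.

    ``positivity_factor`` multiplies the per-cell minimum square median
    to give the vesicle-positivity threshold (the threshold is relative
    because absolute staining intensity varies cell to cell).  The
    default 3x3-px square is 0.238 um^2 at 0.1626 um/px.
    """

    square_px: int = 3
    positivity_factor: float = 2.0
    min_positive_squares: int = 2


@dataclass(frozen=True)
class MaximaParams:
    """Maxima-method settings.

    ``prominence`` is in raw intensity units of the stored bit depth;
    the default 200 presumes 16-bit data and should be scaled down for
    8-bit images.
    """

    prominence: float = 200.0
    min_maxima: int = 2


@dataclass
class SegmentationResult:
    mask: np.ndarray | None
    border_touching: bool
    threshold: float | None
    status: Literal["ok", "segmentation_failed"]


@dataclass(frozen=True)
class DispersionScore:
    """Per-cell dispersion score: NaN distance unless status is 'ok'."""

    cell_id: str
    method: Literal["grid", "maxima"]
    median_pairwise_distance: float
    n_loci: int
    status: Literal["ok", "too_few_loci", "segmentation_failed"]


def huang_threshold(hist: np.ndarray) -> int:
    """Huang-Wang fuzzy threshold of an intensity histogram.

    For each candidate threshold t the image is split into background
    (levels <= t, mean mu0) and foreground (levels > t, mean mu1); each
    level g gets a fuzzy membership ``u(g) = 1 / (1 + |g - mu| / C)``
    to its region's mean, with C the intensity range.  The returned t
    minimizes the total Shannon entropy of the memberships,
    ``sum_g h(g) * S(u(g))`` with ``S(u) = -u ln u - (1-u) ln(1-u)``;
    ties break toward the lower level.  Foreground is ``value > t``.
    """
    hist = np.asarray(hist, dtype=np.float64)
    nz = np.nonzero(hist)[0]
    if len(nz) < 2:
        raise ValueError("histogram has fewer than 2 distinct levels")
    first, last = nz[0], nz[-1]
    C = float(last - first)
    levels = np.arange(len(hist), dtype=np.float64)
    w = np.cumsum(hist)
    wl = np.cumsum(hist * levels)
    total_w, total_wl = w[-1], wl[-1]

    best_t, best_E = None, np.inf
    for t in range(first, last):  # both sides non-empty
        w0 = w[t]
        w1 = total_w - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = wl[t] / w0
        mu1 = (total_wl - wl[t]) / w1
        mu = np.where(levels <= t, mu0, mu1)
        u = 1.0 / (1.0 + np.abs(levels - mu) / C)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = -u * np.log(u) - (1.0 - u) * np.log(1.0 - u)
        s[~np.isfinite(s)] = 0.0  # u = 1 contributes zero entropy
        E = float(np.sum(hist * s))
        if E < best_E - 1e-12:
            best_E, best_t = E, t
    return int(best_t)


def _contrast_stretch(img: np.ndarray, saturated: float = 0.35) -> np.ndarray:
    """Linear stretch to 0..255 saturating `saturated` percent of pixels."""
    lo, hi = np.percentile(img, [saturated / 2.0, 100.0 - saturated / 2.0])
    if hi <= lo:
        return np.zeros_like(img, dtype=np.float64)
    out = (img.astype(np.float64) - lo) / (hi - lo) * 255.0
    return np.clip(out, 0.0, 255.0)


def segment_cell(
    img: np.ndarray, blur_sigma: float = 2.0, saturated: float = 0.35
) -> SegmentationResult:
    """Segment the single cell of a crop.

    A working copy is contrast-stretched, blurred (Gaussian,
    sigma = 2 px), Huang-thresholded, and the largest connected
    foreground component becomes the mask; components touching the
    image border are flagged (cells in contact with the edge are
    excluded from scoring).  Intensity measurements are always taken
    from the unprocessed image.
    """
    if img.max() == img.min():
        return SegmentationResult(None, False, None, "segmentation_failed")
    work = _contrast_stretch(img, saturated)
    work = gaussian_filter(work, blur_sigma)
    quant = np.clip(np.round(work), 0, 255).astype(np.intp)
    hist = np.bincount(quant.ravel(), minlength=256)
    try:
        thr = huang_threshold(hist)
    except ValueError:
        return SegmentationResult(None, False, None, "segmentation_failed")
    fg = quant > thr
    if not fg.any():
        return SegmentationResult(None, False, float(thr), "segmentation_failed")
    lab = label(fg, connectivity=2)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    mask = lab == largest
    border = bool(
        mask[0, :].any() or mask[-1, :].any()
        or mask[:, 0].any() or mask[:, -1].any()
    )
    return SegmentationResult(mask, border, float(thr), "ok")


def grid_dispersion_score(
    img: np.ndarray,
    mask: np.ndarray,
    pixel_size: float,
    p: GridParams = GridParams(),
    cell_id: str = "cell",
) -> DispersionScore:
    """Grid-median dispersion score of one segmented cell.

    The mask's bounding box is tiled into ``square_px`` squares; squares
    whose center pixel lies in the mask are kept and summarized by their
    median raw intensity.  Squares with median above
    ``positivity_factor x (minimum square median of this cell)`` are
    vesicle-positive; the score is the median of all pairwise distances
    between positive-square centroids, in um.
    """
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        return DispersionScore(cell_id, "grid", float("nan"), 0, "segmentation_failed")
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    sq = p.square_px
    half = sq // 2
    centroids: list[tuple[float, float]] = []
    medians: list[float] = []
    for rs in range(r0, r1 + 1, sq):
        for cs in range(c0, c1 + 1, sq):
            rc, cc = rs + half, cs + half
            if rc >= img.shape[0] or cc >= img.shape[1]:
                continue
            if not mask[rc, cc]:
                continue
            block = img[rs : rs + sq, cs : cs + sq]
            medians.append(float(np.median(block)))
            centroids.append((cc * pixel_size, rc * pixel_size))
    if not medians:
        return DispersionScore(cell_id, "grid", float("nan"), 0, "too_few_loci")
    thr = p.positivity_factor * min(medians)
    pos = np.array(
        [c for c, m in zip(centroids, medians) if m >= thr]
    ).reshape(-1, 2)
    if len(pos) < p.min_positive_squares:
        return DispersionScore(
            cell_id, "grid", float("nan"), len(pos), "too_few_loci"
        )
    score = float(np.median(pdist(pos)))
    return DispersionScore(cell_id, "grid", score, len(pos), "ok")


def _plateau_centroid(
    img: np.ndarray, mask: np.ndarray, seed: tuple[int, int]
) -> tuple[float, float]:
    """Centroid (row, col) of the connected equal-value plateau at seed."""
    v = img[seed]
    plateau = (img == v) & mask
    lab = label(plateau, connectivity=2)
    comp = lab == lab[seed]
    rr, cc = np.nonzero(comp)
    return float(rr.mean()), float(cc.mean())


def find_maxima(
    img: np.ndarray,
    mask: np.ndarray | None,
    p: MaximaParams = MaximaParams(),
    pixel_size: float = 1.0,
) -> np.ndarray:
    """Prominence-filtered local maxima inside a mask.

    The prominence of a maximum is its height above the highest saddle
    connecting it to any higher maximum; maxima with prominence
    strictly above ``p.prominence`` are kept, and the global maximum of
    the masked region is always kept.  A connected plateau yields a
    single locus at its centroid.  Returns an (n, 2) array of (x, y)
    in um.

    The implementation floods the image from the top intensity level
    down with a union-find structure: when two catchment components
    meet, the one with the lower peak dies at that saddle and its
    prominence is the peak-minus-saddle height.
    """
    work = np.asarray(img, dtype=np.float64)
    if mask is None:
        mask = np.ones(work.shape, dtype=bool)
    idx = np.nonzero(mask.ravel())[0]
    if len(idx) == 0:
        return np.empty((0, 2))
    h, w = work.shape
    flat = work.ravel()
    order = idx[np.argsort(-flat[idx], kind="stable")]

    parent = np.full(h * w, -1, dtype=np.int64)
    peak_val: dict[int, float] = {}
    # representative pixels, one per distinct peak plateau of the component;
    # equal-height twin peaks stay alive until a strictly higher peak is met
    peak_reps: dict[int, list[int]] = {}
    accepted: list[int] = []

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    def union(a: int, b: int, level: float) -> None:
        ra, rb = find(a), find(b)
        if ra == rb:
            return
        if peak_val[ra] < peak_val[rb]:
            ra, rb = rb, ra
        if peak_val[ra] > peak_val[rb]:
            # rb's peak(s) die at this saddle to a strictly higher maximum
            if peak_val[rb] - level > p.prominence:
                accepted.extend(peak_reps[rb])
        elif peak_val[ra] > level:
            # equal twin peaks joined below their height: both stay alive
            peak_reps[ra].extend(peak_reps[rb])
        # else: one plateau forming at the current level; keep a single rep
        parent[rb] = ra
        del peak_val[rb], peak_reps[rb]

    neigh = [-w - 1, -w, -w + 1, -1, 1, w - 1, w, w + 1]
    pos = 0
    n = len(order)
    while pos < n:
        v = flat[order[pos]]
        end = pos
        while end < n and flat[order[end]] == v:
            end += 1
        batch = order[pos:end]
        for i in batch:
            parent[i] = i
            peak_val[i] = v
            peak_reps[i] = [int(i)]
        for i in batch:
            r, c = divmod(int(i), w)
            for dn in neigh:
                j = i + dn
                jr, jc = divmod(int(j), w)
                if abs(jr - r) > 1 or abs(jc - c) > 1:
                    continue
                if 0 <= j < h * w and parent[j] != -1:
                    union(int(i), int(j), float(v))
        pos = end
    # surviving peaks are global maxima of their connected mask regions
    for reps in peak_reps.values():
        accepted.extend(reps)

    loci = []
    for pix in accepted:
        r, c = divmod(int(pix), w)
        pr, pc = _plateau_centroid(work, mask, (r, c))
        loci.append((pc * pixel_size, pr * pixel_size))
    return np.array(sorted(loci)).reshape(-1, 2)


def maxima_dispersion_score(
    img: np.ndarray,
    mask: np.ndarray | None,
    pixel_size: float,
    p: MaximaParams = MaximaParams(),
    cell_id: str = "cell",
) -> DispersionScore:
    """Median pairwise distance between prominence-filtered maxima, um."""
    loci = find_maxima(img, mask, p, pixel_size)
    if len(loci) < p.min_maxima:
        return DispersionScore(
            cell_id, "maxima", float("nan"), len(loci), "too_few_loci"
        )
    return DispersionScore(
        cell_id, "maxima", float(np.median(pdist(loci))), len(loci), "ok"
    )


def batch_score(
    crops: Iterable[tuple[str, np.ndarray]],
    pixel_size: float,
    method: Literal["grid", "maxima"] = "grid",
    grid_params: GridParams = GridParams(),
    maxima_params: MaximaParams = MaximaParams(),
    exclude_border: bool = True,
) -> pd.DataFrame:
    """Segment and score a batch of single-cell crops.

    Crops whose segmentation fails or touches the image border are
    excluded from scoring but kept in the output with their status, so
    downstream statistics can log the exclusions.
    """
    rows = []
    for cell_id, img in crops:
        seg = segment_cell(img)
        if seg.status != "ok":
            score = DispersionScore(
                cell_id, method, float("nan"), 0, "segmentation_failed"
            )
        elif exclude_border and seg.border_touching:
            score = DispersionScore(
                cell_id, method, float("nan"), 0, "segmentation_failed"
            )
        elif method == "grid":
            score = grid_dispersion_score(
                img, seg.mask, pixel_size, grid_params, cell_id
            )
        else:
            score = maxima_dispersion_score(
                img, seg.mask, pixel_size, maxima_params, cell_id
            )
        rows.append(
            {
                "cell_id": score.cell_id,
                "method": score.method,
                "n_loci": score.n_loci,
                "score_um": score.median_pairwise_distance,
                "status": score.status,
            }
        )
    return pd.DataFrame(
        rows, columns=["cell_id", "method", "n_loci", "score_um", "status"]
    )
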