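"""Independent brute-force oracles used by the test suite.

Everything here is written as directly as possible (explicit loops,
exhaustive search) and stays independent of the package code paths it
checks.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

from amoemig.tracks_io import Spot, Track


def make_track(xy, frame_interval=10.0, track_id=0) -> Track:
    spots = [
        Spot(track_id, i, i * frame_interval, float(x), float(y))
        for i, (x, y) in enumerate(xy)
    ]
    return Track(track_id, spots)


def random_track(rng: np.random.Generator, n: int, frame_interval=10.0) -> Track:
    xy = np.cumsum(rng.normal(0, 2.0, size=(n, 2)), axis=0)
    return make_track(xy, frame_interval)


# ---- trajectory metric oracles (explicit per-step computation) ----

def path_length_oracle(xy) -> float:
    total = 0.0
    for a, b in zip(xy, xy[1:]):
        total += math.hypot(b[0] - a[0], b[1] - a[1])
    return total


def displacement_oracle(xy) -> float:
    return math.hypot(xy[-1][0] - xy[0][0], xy[-1][1] - xy[0][1])


def max_distance_oracle(xy) -> float:
    best = 0.0
    for i in range(len(xy)):
        for j in range(i + 1, len(xy)):
            best = max(
                best, math.hypot(xy[j][0] - xy[i][0], xy[j][1] - xy[i][1])
            )
    return best


def median_speed_oracle(xy, dt) -> float:
    speeds = sorted(
        math.hypot(b[0] - a[0], b[1] - a[1]) / dt for a, b in zip(xy, xy[1:])
    )
    n = len(speeds)
    mid = n // 2
    if n % 2:
        return speeds[mid]
    return 0.5 * (speeds[mid - 1] + speeds[mid])


def dr_curve_oracle(xy) -> list[float]:
    out = []
    run = 0.0
    for t in range(1, len(xy)):
        run += math.hypot(xy[t][0] - xy[t - 1][0], xy[t][1] - xy[t - 1][1])
        d = math.hypot(xy[t][0] - xy[0][0], xy[t][1] - xy[0][1])
        out.append(d / run if run > 0 else float("nan"))
    return out


def msd_oracle(xy) -> list[float]:
    T = len(xy)
    out = []
    for n in range(1, T):
        acc = 0.0
        cnt = 0
        for i in range(T - n):
            dx = xy[i + n][0] - xy[i][0]
            dy = xy[i + n][1] - xy[i][1]
            acc += dx * dx + dy * dy
            cnt += 1
        out.append(acc / cnt)
    return out


# ---- image-analysis oracles ----

def huang_brute(hist) -> int:
    """Exhaustive Huang-Wang fuzziness minimization over all thresholds."""
    hist = np.asarray(hist, dtype=float)
    nz = np.nonzero(hist)[0]
    first, last = nz[0], nz[-1]
    C = float(last - first)
    best_t, best_E = None, np.inf
    for t in range(first, last):
        n0 = hist[: t + 1].sum()
        n1 = hist[t + 1 :].sum()
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / n0
        mu1 = (hist[t + 1 :] * np.arange(t + 1, len(hist))).sum() / n1
        E = 0.0
        for g in range(len(hist)):
            if hist[g] == 0:
                continue
            mu = mu0 if g <= t else mu1
            u = 1.0 / (1.0 + abs(g - mu) / C)
            s = 0.0
            if 0 < u < 1:
                s = -u * math.log(u) - (1 - u) * math.log(1 - u)
            E += hist[g] * s
        if E < best_E - 1e-12:
            best_E, best_t = E, t
    return best_t


def prominence_maxima_brute(img, prominence, mask=None):
    """Exhaustive prominence by threshold-descent saddle search.

    For each local-maximum plateau, descend through all intensity
    levels until the connected super-level component containing the
    plateau holds a strictly higher pixel; that level is the key
    saddle.  Returns sorted (x, y) pixel coordinates of plateau
    centroids with prominence strictly above the cutoff (global maxima
    have infinite prominence).
    """
    from skimage.measure import label as sklabel

    img = np.asarray(img, dtype=float)
    h, w = img.shape
    if mask is None:
        mask = np.ones((h, w), bool)
    work = np.where(mask, img, -np.inf)
    seen = np.zeros((h, w), bool)
    plateaus = []
    for r in range(h):
        for c in range(w):
            if seen[r, c] or not mask[r, c]:
                continue
            v = work[r, c]
            comp = []
            q = deque([(r, c)])
            seen[r, c] = True
            while q:
                a, b = q.popleft()
                comp.append((a, b))
                for da in (-1, 0, 1):
                    for db in (-1, 0, 1):
                        na, nb = a + da, b + db
                        if (
                            0 <= na < h and 0 <= nb < w
                            and not seen[na, nb] and mask[na, nb]
                            and work[na, nb] == v
                        ):
                            seen[na, nb] = True
                            q.append((na, nb))
            is_max = all(
                not (0 <= a + da < h and 0 <= b + db < w)
                or work[a + da, b + db] <= v
                for a, b in comp
                for da in (-1, 0, 1)
                for db in (-1, 0, 1)
            )
            if is_max:
                plateaus.append((v, comp))
    out = []
    levels = sorted(set(work[mask].ravel()), reverse=True)
    for v, comp in plateaus:
        prom = np.inf
        for t in levels:
            if t > v:
                continue
            cc = sklabel((work >= t) & mask, connectivity=2)
            lid = cc[comp[0]]
            if (work[cc == lid] > v).any():
                prom = v - t
                break
        if prom > prominence:
            rr = float(np.mean([a for a, b in comp]))
            ccm = float(np.mean([b for a, b in comp]))
            out.append((ccm, rr))
    return np.array(sorted(out)).reshape(-1, 2)
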