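"""Independent brute-force reference implementations used only by tests.

Each function re-derives a pipeline stage with the most literal algorithm
available — explicit neighborhood loops, exhaustive pairwise distances,
O(n^3) agglomeration — so the package implementation can be checked against
code that shares none of its machinery.
"""
from __future__ import annotations

import itertools

import numpy as np


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    """Integer offsets of a discrete disc footprint (matches skimage disk)."""
    r = int(radius)
    return [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= r * r
    ]


def brute_erosion(img: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale erosion by explicit min over the disc, with edge-symmetric
    padding (the boundary convention of ndimage's reflect mode)."""
    h, w = img.shape
    r = int(radius)
    pad = np.pad(img, r, mode="symmetric")
    out = np.empty_like(img)
    offs = disk_offsets(r)
    for y in range(h):
        for x in range(w):
            out[y, x] = min(pad[y + r + dy, x + r + dx] for dy, dx in offs)
    return out


def brute_dilation(img: np.ndarray, radius: int) -> np.ndarray:
    h, w = img.shape
    r = int(radius)
    pad = np.pad(img, r, mode="symmetric")
    out = np.empty_like(img)
    offs = disk_offsets(r)
    for y in range(h):
        for x in range(w):
            out[y, x] = max(pad[y + r + dy, x + r + dx] for dy, dx in offs)
    return out


def brute_opening(img: np.ndarray, radius: int) -> np.ndarray:
    """Erosion followed by dilation."""
    return brute_dilation(brute_erosion(img, radius), radius)


def brute_edt(mask: np.ndarray) -> np.ndarray:
    """Exhaustive Euclidean distance transform: per foreground pixel, the
    distance to the nearest background pixel of the array (infinite when
    the mask has no background)."""
    h, w = mask.shape
    bg = [(y, x) for y in range(h) for x in range(w) if not mask[y, x]]
    out = np.zeros((h, w), dtype=float)
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            d2 = min(((y - by) ** 2 + (x - bx) ** 2) for by, bx in bg) if bg else np.inf
            out[y, x] = np.sqrt(d2)
    return out


def brute_edt_maxima(mask: np.ndarray, min_distance: float) -> list[tuple[float, float]]:
    """Exhaustive distance-map maxima with plateau collapse.

    A pixel is a peak iff no pixel within min_distance has a strictly larger
    EDT value; 8-connected peak pixels form plateaus, reported as centroids
    (x, y).
    """
    edt = brute_edt(mask)
    h, w = mask.shape
    r = int(np.ceil(min_distance))
    peaks = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            is_peak = True
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    if dy * dy + dx * dx > min_distance * min_distance:
                        continue
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and edt[yy, xx] > edt[y, x]:
                        is_peak = False
                        break
                if not is_peak:
                    break
            peaks[y, x] = is_peak

    # group 8-connected plateau pixels with a flood fill
    seen = np.zeros_like(peaks)
    out = []
    for y in range(h):
        for x in range(w):
            if not peaks[y, x] or seen[y, x]:
                continue
            stack = [(y, x)]
            seen[y, x] = True
            members = []
            while stack:
                cy, cx = stack.pop()
                members.append((cy, cx))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = cy + dy, cx + dx
                        if 0 <= yy < h and 0 <= xx < w and peaks[yy, xx] and not seen[yy, xx]:
                            seen[yy, xx] = True
                            stack.append((yy, xx))
            ys = [m[0] for m in members]
            xs = [m[1] for m in members]
            out.append((float(np.mean(xs)), float(np.mean(ys))))
    return out


def brute_greedy_suppression(candidates, min_dist: float) -> list[int]:
    """Literal greedy rule: visit candidates by descending value (ties:
    larger area, then row-major y, x); accept unless within min_dist of an
    accepted candidate. ``candidates`` is a list of (x, y, value, area)."""
    order = sorted(
        range(len(candidates)),
        key=lambda i: (
            -candidates[i][2],
            -candidates[i][3],
            candidates[i][1],
            candidates[i][0],
        ),
    )
    accepted: list[int] = []
    for i in order:
        xi, yi = candidates[i][0], candidates[i][1]
        if all(
            (xi - candidates[j][0]) ** 2 + (yi - candidates[j][1]) ** 2 >= min_dist**2
            for j in accepted
        ):
            accepted.append(i)
    return accepted


def brute_knn(points: np.ndarray, ref: int, k: int) -> np.ndarray:
    """k smallest Euclidean distances from points[ref] to the other points."""
    d = np.sqrt(((points - points[ref]) ** 2).sum(axis=1))
    d = np.delete(d, ref)
    return np.sort(d)[:k]


def brute_upgma(data: np.ndarray):
    """O(n^3) unweighted average-linkage agglomeration.

    At each step recomputes every inter-cluster distance as the mean of all
    pairwise Euclidean distances between original members, merges the
    closest pair (ties: smallest member indices), and records
    (members_a, members_b, height). Returns the merge list.
    """
    n = len(data)
    pair_d = np.sqrt(((data[:, None, :] - data[None, :, :]) ** 2).sum(-1))
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca, cb = clusters[a], clusters[b]
            d = np.mean([pair_d[i, j] for i in ca for j in cb])
            key = (d, tuple(sorted(ca)), tuple(sorted(cb)))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _, _), a, b = best
        merges.append((clusters[a], clusters[b], d))
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges
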