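"""Independent brute-force reference implementations used only by tests.

Each oracle is written for clarity, not speed, and shares no code with the
pipeline implementations it checks (only the public parameter objects).
"""

from __future__ import annotations

import math

import numpy as np

EARTH_R = 6_371_000.0


def hav(lat1, lon1, lat2, lon2):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    a = math.sin((p2 - p1) / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_R * math.asin(math.sqrt(a))


# ---------------------------------------------------------------- convex hull
def brute_force_hull(points: np.ndarray):
    """O(n^3) convex hull of planar points: a directed pair (i, j) is a hull
    edge iff every other point lies on its left or on the segment. Returns
    (area, perimeter, vertices in counterclockwise order)."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    n = len(pts)
    if n == 1:
        return 0.0, 0.0, pts
    edges = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a, b = pts[i], pts[j]
            good = True
            strictly_left = False
            for k in range(n):
                if k in (i, j):
                    continue
                ab = b - a
                ap = pts[k] - a
                cr = ab[0] * ap[1] - ab[1] * ap[0]
                if cr < -1e-9 * max(1.0, np.abs(pts).max() ** 2):
                    good = False
                    break
                if cr > 0:
                    strictly_left = True
            if good and strictly_left:
                edges[i] = j
    if not edges:  # all collinear: "hull" is the extreme segment
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        return 0.0, float(d.max()), pts
    start = next(iter(edges))
    order = [start]
    cur = edges[start]
    while cur != start:
        order.append(cur)
        cur = edges[cur]
    verts = pts[order]
    x, y = verts[:, 0], verts[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    perim = float(np.sum(np.linalg.norm(verts - np.roll(verts, -1, axis=0), axis=1)))
    return float(area), perim, verts


# ------------------------------------------------------------------ non-wear
def choi_window_scan(counts: np.ndarray, window: int = 90, allowance: int = 2,
                     flank: int = 30) -> np.ndarray:
    """Wear flags by literally scanning every ``window``-epoch window.

    A window qualifies as non-wear when every nonzero epoch inside belongs
    to an interruption run of at most ``allowance`` epochs with at least
    ``flank`` consecutive zero epochs immediately before and after it (in
    the full series). All epochs of qualifying windows are non-wear.
    """
    c = np.asarray(counts, dtype=float)
    n = c.size
    nz = c != 0
    # zeros_before[i]/zeros_after[i]: consecutive zeros adjacent to epoch i
    zeros_before = np.zeros(n, dtype=int)
    run = 0
    for i in range(n):
        zeros_before[i] = run
        run = run + 1 if not nz[i] else 0
    zeros_after = np.zeros(n, dtype=int)
    run = 0
    for i in range(n - 1, -1, -1):
        zeros_after[i] = run
        run = run + 1 if not nz[i] else 0
    # run id and length for nonzero runs
    run_start = np.full(n, -1)
    run_len = np.zeros(n, dtype=int)
    i = 0
    while i < n:
        if nz[i]:
            j = i
            while j < n and nz[j]:
                j += 1
            run_start[i:j] = i
            run_len[i:j] = j - i
            i = j
        else:
            i += 1
    csum = np.concatenate([[0], np.cumsum(nz)])

    nonwear = np.zeros(n, dtype=bool)
    for s in range(0, n - window + 1):
        e = s + window
        k = csum[e] - csum[s]
        if k == 0:
            nonwear[s:e] = True
            continue
        ok = True
        for i in range(s, e):
            if not nz[i]:
                continue
            r0 = run_start[i]
            rl = run_len[i]
            if rl > allowance:
                ok = False
                break
            if zeros_before[r0] < flank or zeros_after[r0 + rl - 1] < flank:
                ok = False
                break
        if ok:
            nonwear[s:e] = True
    return ~nonwear


# -------------------------------------------------------------- segmentation
def naive_grow(lat, lon, start, end, radius):
    """Largest j with candidate [start..j] valid, re-checking every member
    against the from-scratch median at every step."""
    j = start
    while j + 1 <= end:
        k = j + 1
        mlat = float(np.median(lat[start:k + 1]))
        mlon = float(np.median(lon[start:k + 1]))
        if max(hav(lat[i], lon[i], mlat, mlon) for i in range(start, k + 1)) > radius:
            return j
        j = k
    return j


def naive_stop_ranges(lat, lon, t, radius, min_duration_s):
    stops = []
    i = 0
    n = len(lat)
    while i < n:
        j = naive_grow(lat, lon, i, n - 1, radius)
        if t[j] - t[i] >= min_duration_s:
            stops.append((i, j))
            i = j + 1
        else:
            i += 1
    return stops
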