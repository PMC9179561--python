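"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the library code paths they check: the hull
oracle is a Jarvis march plus the shoelace formula, point-in-polygon is a
ray cast with explicit on-segment handling, and the Kruskal-Wallis
p-value oracle enumerates every group relabelling.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def jarvis_hull(points: np.ndarray) -> np.ndarray:
    """Gift-wrapping convex hull (CCW) robust to collinear points."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) <= 2:
        return pts
    start = pts[np.lexsort((pts[:, 0], pts[:, 1]))][0]
    hull = [start]
    cur = start
    while True:
        nxt = None
        for p in pts:
            if np.array_equal(p, cur):
                continue
            if nxt is None:
                nxt = p
                continue
            a, b = nxt - cur, p - cur
            cr = a[0] * b[1] - a[1] * b[0]
            if cr < 0 or (cr == 0 and np.linalg.norm(p - cur) > np.linalg.norm(nxt - cur)):
                nxt = p
        if np.array_equal(nxt, hull[0]):
            break
        hull.append(nxt)
        cur = nxt
        if len(hull) > len(pts):  # pragma: no cover - defensive
            raise RuntimeError("gift wrapping failed to close")
    return np.asarray(hull)


def shoelace_area(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def hull_area_of_mask(pixels: np.ndarray) -> float:
    """Brute-force A_p in px^2: hull of all pixel-square corners + shoelace."""
    pixels = np.asarray(pixels)
    rows, cols = pixels[:, 0], pixels[:, 1]
    xs = np.concatenate([cols, cols + 1, cols, cols + 1]).astype(float)
    ys = np.concatenate([rows, rows, rows + 1, rows + 1]).astype(float)
    return shoelace_area(jarvis_hull(np.column_stack([xs, ys])))


def _on_segment(px, py, ax, ay, bx, by, eps=1e-12) -> bool:
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    if abs(cross) > eps:
        return False
    dot = (px - ax) * (bx - ax) + (py - ay) * (by - ay)
    if dot < -eps:
        return False
    sq = (bx - ax) ** 2 + (by - ay) ** 2
    return dot <= sq + eps


def point_in_polygon(px: float, py: float, vertices: np.ndarray) -> bool:
    """Ray casting with boundary points counted as inside."""
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    inside = False
    for i in range(n):
        ax, ay = v[i]
        bx, by = v[(i + 1) % n]
        if _on_segment(px, py, ax, ay, bx, by):
            return True
        if (ay > py) != (by > py):
            x_int = ax + (py - ay) * (bx - ax) / (by - ay)
            if px < x_int:
                inside = not inside
    return inside


def kw_statistic(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H, written independently for the oracle."""
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    ssum = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        ssum += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (N * (N + 1)) * ssum - 3 * (N + 1)
    corr = 1 - ((counts**3 - counts).sum()) / (N**3 - N)
    return H / corr


def kw_permutation_p(groups: list[np.ndarray]) -> float:
    """Exact permutation p-value of H by enumerating all group relabellings."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    H_obs = kw_statistic(groups)
    idx_all = list(range(len(pooled)))
    count = 0
    total = 0
    for g1 in combinations(idx_all, sizes[0]):
        rest1 = [i for i in idx_all if i not in g1]
        for g2 in combinations(rest1, sizes[1]):
            g3 = [i for i in rest1 if i not in g2]
            parts = [pooled[list(g1)], pooled[list(g2)], pooled[g3]]
            if kw_statistic(parts) >= H_obs - 1e-12:
                count += 1
            total += 1
    return count / total
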