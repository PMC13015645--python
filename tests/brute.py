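"""Independent brute-force oracles used by the tests.

Everything here is deliberately written from first principles (plain
numpy/math, no shapely) so it cannot share a code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def point_segment_distance(px, py, ax, ay, bx, by) -> float:
    """Euclidean distance from point to segment AB, interior projection."""
    abx, aby = bx - ax, by - ay
    denom = abx * abx + aby * aby
    if denom == 0:
        return math.hypot(px - ax, py - ay)
    t = ((px - ax) * abx + (py - ay) * aby) / denom
    t = min(1.0, max(0.0, t))
    cx, cy = ax + t * abx, ay + t * aby
    return math.hypot(px - cx, py - cy)


def point_polyline_distance(px, py, coords) -> float:
    """Min distance from a point to a polyline given as [(x, y), ...]."""
    best = math.inf
    for (ax, ay), (bx, by) in zip(coords[:-1], coords[1:]):
        best = min(best, point_segment_distance(px, py, ax, ay, bx, by))
    return best


def dense_sample_polyline_distance(px, py, coords, spacing=1.0) -> float:
    """Distance via dense sampling of points along the polyline."""
    best = math.inf
    for (ax, ay), (bx, by) in zip(coords[:-1], coords[1:]):
        seg_len = math.hypot(bx - ax, by - ay)
        n = max(2, int(math.ceil(seg_len / spacing)) + 1)
        ts = np.linspace(0.0, 1.0, n)
        xs = ax + ts * (bx - ax)
        ys = ay + ts * (by - ay)
        best = min(best, float(np.min(np.hypot(xs - px, ys - py))))
    return best


def exposure_formula(px, py, road_coord_lists, params, hotspots=()) -> float:
    """Direct evaluation of the outdoor exposure model at one point."""
    conc = params.background
    if road_coord_lists and params.traffic_amplitude > 0:
        d = min(point_polyline_distance(px, py, c) for c in road_coord_lists)
        conc += params.traffic_amplitude * math.exp(-d / params.traffic_decay_length)
    for (hx, hy, amp, dlen) in hotspots:
        conc += amp * math.exp(-math.hypot(px - hx, py - hy) / dlen)
    return conc


def weighted_mean(values, weights) -> float:
    """Scalar-loop weighted mean."""
    num = 0.0
    den = 0.0
    for v, w in zip(values, weights):
        num += v * w
        den += w
    return num / den


def midranks(values) -> list[float]:
    """Average ranks with ties, computed by explicit grouping."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_rho(x, y) -> float:
    """Pearson correlation of midranks, from the explicit formula."""
    rx = midranks(list(x))
    ry = midranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def permutation_p(x, y, n_perm=100_000, seed=0) -> float:
    """Two-sided Monte-Carlo permutation p-value for Spearman rho."""
    rng = np.random.default_rng(seed)
    rx = np.array(midranks(list(x)))
    ry = np.array(midranks(list(y)))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    obs = abs(float((rx * ry).sum()) / denom)
    perm_idx = np.argsort(rng.random((n_perm, rx.size)), axis=1)
    rhos = (ry[perm_idx] @ rx) / denom
    return float(np.mean(np.abs(rhos) >= obs - 1e-12))
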