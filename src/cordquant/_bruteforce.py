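"""Small brute-force reference implementations.

These are deliberately naive, independent re-derivations of results the
main modules compute by faster or more structured means; they exist so
that tests and the verification script can cross-check the production
code paths against exhaustive enumeration.  None of them is used by the
pipeline itself.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np

__all__ = [
    "exhaustive_min_cost_partition",
    "flood_fill_particle_count",
    "otsu_exhaustive",
]


def _pairwise_ok(points, cluster, radius):
    r2 = radius * radius
    for a, b in combinations(cluster, 2):
        if points[a][0] == points[b][0]:
            return False  # one point per source
        dx = points[a][1] - points[b][1]
        dy = points[a][2] - points[b][2]
        if dx * dx + dy * dy > r2:
            return False
    return True


def _cluster_cost(points, cluster):
    return sum(
        float(np.hypot(points[a][1] - points[b][1], points[a][2] - points[b][2]))
        for a, b in combinations(cluster, 2)
    )


def _partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def exhaustive_min_cost_partition(
    sets: Sequence, radius: float
) -> tuple[int, float, list[list[tuple[int, int]]]]:
    """Optimal overlap of K point sets by exhaustive enumeration.

    Points are identified as (source_idx, point_idx).  Among all
    partitions whose blocks take at most one point per source and stay
    pairwise within ``radius``, returns the one minimising
    (number of objects, total within-object pairwise distance).

    The search first splits the points into connected components of the
    radius graph (blocks can never span components), then enumerates
    set partitions inside each component — feasible only for the small
    instances this oracle is meant for.
    """
    points = []  # (source_idx, x, y)
    ids = []
    for si, ds in enumerate(sets):
        for pi in range(len(ds)):
            points.append((si, float(ds.x[pi]), float(ds.y[pi])))
            ids.append((si, pi))
    n = len(points)

    # connected components of the radius graph
    adj = [[] for _ in range(n)]
    r2 = radius * radius
    for i, j in combinations(range(n), 2):
        dx = points[i][1] - points[j][1]
        dy = points[i][2] - points[j][2]
        if dx * dx + dy * dy <= r2:
            adj[i].append(j)
            adj[j].append(i)
    seen = [False] * n
    components = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        components.append(comp)

    total_objects, total_cost = 0, 0.0
    blocks_out: list[list[tuple[int, int]]] = []
    for comp in components:
        best = None
        for part in _partitions(comp):
            if not all(_pairwise_ok(points, blk, radius) for blk in part):
                continue
            cost = sum(_cluster_cost(points, blk) for blk in part)
            key = (len(part), cost)
            if best is None or key < best[0]:
                best = (key, part)
        assert best is not None  # singletons are always feasible
        total_objects += best[0][0]
        total_cost += best[0][1]
        blocks_out.extend([[ids[m] for m in blk] for blk in best[1]])
    return total_objects, total_cost, blocks_out


def flood_fill_particle_count(
    binary: np.ndarray, min_area_px: float
) -> tuple[int, list[float]]:
    """Count 8-connected particles strictly above an area cut.

    Plain stack-based flood fill; independent of any labelling library.
    Returns (count, centroid-free list of particle pixel areas).
    """
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    visited = np.zeros_like(binary)
    areas = []
    for i0 in range(h):
        for j0 in range(w):
            if not binary[i0, j0] or visited[i0, j0]:
                continue
            stack = [(i0, j0)]
            visited[i0, j0] = True
            area = 0
            while stack:
                i, j = stack.pop()
                area += 1
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < h and 0 <= jj < w and binary[ii, jj] and not visited[ii, jj]:
                            visited[ii, jj] = True
                            stack.append((ii, jj))
            areas.append(float(area))
    kept = [a for a in areas if a > min_area_px]
    return len(kept), kept


def between_class_variance(channel: np.ndarray, t: float) -> float:
    """Weighted between-class variance of the two classes split at t."""
    channel = np.asarray(channel, dtype=float).ravel()
    fg = channel > t
    if not fg.any() or fg.all():
        return 0.0
    w1 = fg.mean()
    w0 = 1.0 - w1
    return float(w0 * w1 * (channel[~fg].mean() - channel[fg].mean()) ** 2)


def otsu_exhaustive(channel: np.ndarray, n_bins: int = 256) -> float:
    """Otsu threshold by exhaustive between-class-variance maximisation.

    Scans every histogram cut over ``n_bins`` equal-width bins and
    returns the bin-centre cut maximising the between-class variance.
    """
    channel = np.asarray(channel, dtype=float).ravel()
    lo, hi = channel.min(), channel.max()
    if hi == lo:
        return float(hi)
    hist, edges = np.histogram(channel, bins=n_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    best_t, best_var = centers[0], -1.0
    total = hist.sum()
    for cut in range(1, n_bins):
        w0 = hist[:cut].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:cut] * centers[:cut]).sum() / w0
        mu1 = (hist[cut:] * centers[cut:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var = var
            best_t = (centers[cut - 1] + centers[cut]) / 2
    return float(best_t)
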