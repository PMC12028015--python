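"""Multi-analysis overlap of point identifications and consensus counts.

Several analyses of the same section — repeated manual passes by one or
more observers, a threshold macro, a probability-map classifier — each
yield a point set of putative neurons.  Overlapping them partitions all
points into *objects*; each object carries an agreement class k, the
number of manual analyses (out of K) that identified it.  Class K
objects are near-certain neurons; class 1 objects are doubtful; class 0
objects were proposed only by automated methods and are usually
artifacts.

The consensus count used as an accuracy reference (the Reference Number
of Neurons, RNN) weights every object by its agreement fraction k/K,
which makes it algebraically identical to the mean of the K per-analyst
counts.

The matcher links points across sets greedily by increasing distance
under three constraints: pairs further apart than the linking radius
are never merged, an object takes at most one point per source, and all
points inside an object stay pairwise within the radius.  An exhaustive
minimum-cost partition is kept in :mod:`cordquant._bruteforce` as an
independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .detect import DetectionSet

__all__ = [
    "MatchedObject",
    "AgreementTable",
    "ConsensusResult",
    "match_detection_sets",
    "agreement_histogram",
    "reference_number_of_neurons",
    "method_overlap_stats",
]


@dataclass(frozen=True)
class MatchedObject:
    """One consensus object: contributing points keyed by source id."""

    x: float  # centroid of contributing points, µm
    y: float
    contributions: dict[str, tuple[float, float]]

    @property
    def k(self) -> int:
        return len(self.contributions)


@dataclass(frozen=True)
class AgreementTable:
    """All matched objects from K analyses of one section."""

    objects: tuple[MatchedObject, ...]
    sources: tuple[str, ...]  # ordered manual source ids
    radius: float  # linking radius used, µm
    section_id: str = ""

    @property
    def K(self) -> int:
        return len(self.sources)

    def __len__(self) -> int:
        return len(self.objects)

    def class_counts(self) -> np.ndarray:
        """n_k for k = 0..K (k=0 is always 0 for purely manual tables)."""
        out = np.zeros(self.K + 1, dtype=int)
        for obj in self.objects:
            out[obj.k] += 1
        return out

    def per_source_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in self.sources}
        for obj in self.objects:
            for s in obj.contributions:
                counts[s] += 1
        return counts


@dataclass(frozen=True)
class ConsensusResult:
    """Weighted-consensus reference count plus the class histogram."""

    rnn: float
    class_frequencies: np.ndarray  # n_0..n_K

    @property
    def n_objects(self) -> int:
        return int(self.class_frequencies.sum())


def _pair_candidates(pts, radius):
    """Sorted candidate links between points of different sources.

    Sort key: distance, then source indices, then coordinates — ties
    are resolved by geometry rather than input order so the partition
    is stable under permutations of the input sets.
    """
    xy = np.array([[p[2], p[3]] for p in pts])
    tree = cKDTree(xy)
    cands = []
    for i, j in tree.query_pairs(radius):
        if pts[i][0] == pts[j][0]:
            continue  # same source never links
        d = float(np.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1]))
        a, b = (i, j) if (pts[i][0], pts[i][2], pts[i][3]) <= (pts[j][0], pts[j][2], pts[j][3]) else (j, i)
        cands.append((d, pts[a][0], pts[b][0], pts[a][2], pts[a][3], pts[b][2], pts[b][3], a, b))
    cands.sort(key=lambda c: c[:7])
    return cands


def match_detection_sets(
    sets: Sequence[DetectionSet],
    radius: float = 10.0,
) -> AgreementTable:
    """Partition the union of K point sets into matched objects.

    Greedy agglomeration by increasing link distance with a union-find;
    two clusters merge only when their source sets are disjoint and
    every cross-pair of member points lies within ``radius``.  Every
    input point ends up in exactly one object.
    """
    if len(sets) == 0:
        raise ValueError("need at least one detection set")
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    sources = tuple(ds.source_id or f"set{i}" for i, ds in enumerate(sets))
    if len(set(sources)) != len(sources):
        raise ValueError("detection sets must have distinct source_id")

    pts = []  # (source_idx, point_idx, x, y)
    for si, ds in enumerate(sets):
        for pi in range(len(ds)):
            pts.append((si, pi, float(ds.x[pi]), float(ds.y[pi])))

    parent = list(range(len(pts)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    members: dict[int, list[int]] = {i: [i] for i in range(len(pts))}
    srcsets: dict[int, set[int]] = {i: {pts[i][0]} for i in range(len(pts))}

    if pts:
        r2 = radius * radius
        for cand in _pair_candidates(pts, radius):
            i, j = cand[7], cand[8]
            ri, rj = find(i), find(j)
            if ri == rj or srcsets[ri] & srcsets[rj]:
                continue
            ok = True
            for a in members[ri]:
                for b in members[rj]:
                    dx = pts[a][2] - pts[b][2]
                    dy = pts[a][3] - pts[b][3]
                    if dx * dx + dy * dy > r2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            parent[rj] = ri
            members[ri].extend(members[rj])
            srcsets[ri] |= srcsets[rj]
            del members[rj], srcsets[rj]

    objects = []
    for root, mem in members.items():
        contrib = {
            sources[pts[m][0]]: (pts[m][2], pts[m][3]) for m in sorted(mem)
        }
        xs = [pts[m][2] for m in mem]
        ys = [pts[m][3] for m in mem]
        objects.append(MatchedObject(float(np.mean(xs)), float(np.mean(ys)), contrib))
    objects.sort(key=lambda o: (o.x, o.y))

    section_id = next((ds.section_id for ds in sets if ds.section_id), "")
    return AgreementTable(tuple(objects), sources, float(radius), section_id)


def _match_points_to_objects(
    det: DetectionSet, table: AgreementTable, radius: float
) -> np.ndarray:
    """Greedy one-to-one match of method points to table objects.

    Returns, per point, the matched object index or -1.  Pairs are
    taken by increasing distance.
    """
    n_obj = len(table.objects)
    matched = np.full(len(det), -1, dtype=int)
    if n_obj == 0 or len(det) == 0:
        return matched
    obj_xy = np.array([[o.x, o.y] for o in table.objects])
    pt_xy = np.column_stack([det.x, det.y])
    tree = cKDTree(obj_xy)
    pairs = []
    for pi, neigh in enumerate(tree.query_ball_point(pt_xy, radius)):
        for oi in neigh:
            d = float(np.hypot(*(pt_xy[pi] - obj_xy[oi])))
            pairs.append((d, pi, oi))
    pairs.sort()
    obj_used = np.zeros(n_obj, dtype=bool)
    for d, pi, oi in pairs:
        if matched[pi] >= 0 or obj_used[oi]:
            continue
        matched[pi] = oi
        obj_used[oi] = True
    return matched


def agreement_histogram(
    table: AgreementTable,
    extra_sets: Sequence[DetectionSet] | None = None,
    *,
    normalize: bool = False,
) -> np.ndarray:
    """Class frequencies n_0..n_K of the matched objects.

    Class k counts objects identified in k manual analyses.  Class 0
    counts objects contributed only by the automated ``extra_sets``:
    extra detections are matched one-to-one to manual objects within
    the table's linking radius, and the leftovers are clustered among
    themselves into class-0 objects.  With ``normalize=True`` the
    frequencies are scaled so the manual classes (k ≥ 1) sum to 100.
    """
    freqs = table.class_counts().astype(float)
    if extra_sets:
        leftovers = []
        for ds in extra_sets:
            m = _match_points_to_objects(ds, table, table.radius)
            unmatched = m < 0
            if unmatched.any():
                leftovers.append(
                    DetectionSet(
                        x=ds.x[unmatched], y=ds.y[unmatched],
                        source_id=ds.source_id or "extra", section_id=ds.section_id,
                    )
                )
        if leftovers:
            extra_table = match_detection_sets(leftovers, radius=table.radius)
            freqs[0] += len(extra_table.objects)
    if normalize:
        manual_total = freqs[1:].sum()
        if manual_total > 0:
            freqs = freqs * (100.0 / manual_total)
    return freqs


def reference_number_of_neurons(table: AgreementTable) -> float:
    """Weighted consensus count: each object contributes k/K.

    Equal, by point conservation, to the arithmetic mean of the K
    per-analyst counts.
    """
    if table.K < 1:
        raise ValueError("need at least one manual analysis")
    return float(sum(obj.k for obj in table.objects)) / table.K


def consensus_result(
    table: AgreementTable, extra_sets: Sequence[DetectionSet] | None = None
) -> ConsensusResult:
    return ConsensusResult(
        rnn=reference_number_of_neurons(table),
        class_frequencies=agreement_histogram(table, extra_sets),
    )


def method_overlap_stats(
    method_set: DetectionSet,
    table: AgreementTable,
    radius: float | None = None,
) -> dict:
    """How an automated method's detections overlap the manual objects.

    Returns per-class detection fractions (for k = 1..K, the fraction
    of class-k manual objects matched by the method within ``radius``)
    and the percentage of method detections not matching any manual
    object, relative to the number of manual objects.
    """
    r = table.radius if radius is None else float(radius)
    matched = _match_points_to_objects(method_set, table, r)
    hit = np.zeros(len(table.objects), dtype=bool)
    hit[matched[matched >= 0]] = True

    fractions: dict[int, float] = {}
    for k in range(1, table.K + 1):
        idx = [i for i, o in enumerate(table.objects) if o.k == k]
        fractions[k] = float(np.mean(hit[idx])) if idx else float("nan")

    n_manual = sum(1 for o in table.objects if o.k >= 1)
    n_extra = int((matched < 0).sum())
    extra_pct = 100.0 * n_extra / n_manual if n_manual else 0.0
    return {
        "detection_fraction_by_class": fractions,
        "extra_percent": extra_pct,
        "n_extra": n_extra,
        "n_manual_objects": n_manual,
    }
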