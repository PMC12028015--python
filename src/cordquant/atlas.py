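"""Procedural toy atlas of a spinal cord cross-section.

The grey matter of a thoracic spinal cord section has a characteristic
butterfly shape: a central column around the central canal with paired
dorsal and ventral horns.  Cytoarchitectonically the grey matter is
partitioned into Rexed laminae (L1 dorsal ... L10 around the canal) plus
a handful of named nuclei (Clarke's dorsal nucleus D, the intercalated
nucleus ICI, the intermediolateral IML and intermediomedial IMM columns,
and the lumbar dorsal commissural nucleus LDCom).

This module builds a deterministic, geometrically simple stand-in for
such a regionalised section: a butterfly-symmetric outline partitioned
into horizontal laminar bands with small circular nuclei carved out.  It
is intentionally schematic — it gives the downstream registration and
quantification stages a region map with the right topology (simple,
non-overlapping polygons covering the grey matter) without pretending to
anatomical accuracy.

All coordinates are in micrometres, origin at the top-left corner of the
frame, y increasing ventrally (downward on screen).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

__all__ = ["Region", "ToyAtlas", "build_toy_atlas"]

#: order in which nuclei are appended after the laminae; also the
#: boundary tie-break order used by region assignment.
NUCLEUS_IDS = ("D", "ICI", "IMM", "IML", "LDCom")

_CIRCLE_SEGMENTS = 48  # vertices per full circle in procedural discs


@dataclass(frozen=True)
class Region:
    """A named atlas region: a simple closed polygon in µm."""

    region_id: str
    vertices: np.ndarray  # (n, 2) float array, closed ring (first != last)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_um2(self) -> float:
        return float(self.polygon.area)


@dataclass(frozen=True)
class ToyAtlas:
    """Regionalised grey-matter map of one section.

    ``regions`` are pairwise non-overlapping simple polygons, all inside
    ``grey_outline``; their order defines the boundary tie-break used
    when assigning detections to regions.
    """

    regions: tuple[Region, ...]
    grey_outline: np.ndarray  # (n, 2) closed ring
    frame_um: tuple[float, float]  # (width, height)

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate region_id in atlas")

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    @property
    def outline_polygon(self) -> Polygon:
        return Polygon(self.grey_outline)

    def region(self, region_id: str) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)

    def region_areas_um2(self) -> dict[str, float]:
        return {r.region_id: r.area_um2 for r in self.regions}


def _ellipse(cx: float, cy: float, rx: float, ry: float) -> Polygon:
    disc = Point(cx, cy).buffer(1.0, quad_segs=_CIRCLE_SEGMENTS // 4)
    return affinity.scale(disc, rx, ry, origin=(cx, cy))


def _as_single_polygon(geom, what: str) -> Polygon:
    if isinstance(geom, Polygon):
        poly = geom
    else:
        parts = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
        if len(parts) != 1:
            raise ValueError(f"{what}: expected a single connected polygon")
        poly = parts[0]
    if poly.interiors:
        raise ValueError(f"{what}: polygon has holes")
    return poly


def _ring(poly: Polygon) -> np.ndarray:
    coords = np.asarray(poly.exterior.coords, dtype=float)
    return coords[:-1]  # drop duplicated closing vertex


def build_toy_atlas(frame_um: tuple[float, float], n_laminae: int = 10) -> ToyAtlas:
    """Build the butterfly grey-matter outline and its regionalisation.

    Parameters
    ----------
    frame_um
        (width, height) of the section frame in µm.
    n_laminae
        Number of horizontal laminar bands (named ``L1`` dorsal to
        ``L{n}`` ventral); must lie in [3, 15].

    Returns
    -------
    ToyAtlas
        Laminae first, then the five nuclei.  Deterministic: identical
        inputs give identical vertex lists.
    """
    w, h = float(frame_um[0]), float(frame_um[1])
    if w <= 0 or h <= 0:
        raise ValueError(f"frame dimensions must be positive, got {frame_um}")
    if not (3 <= int(n_laminae) <= 15):
        raise ValueError(f"n_laminae must be in [3, 15], got {n_laminae}")
    n_laminae = int(n_laminae)

    cx = w / 2.0
    y_top, y_bot = 0.06 * h, 0.94 * h

    # Butterfly: central column plus mirrored dorsal and ventral horns.
    # Horn centres sit inside the column half-width, so every horizontal
    # slice of every ellipse overlaps the column and any band cut stays
    # a single connected polygon.
    column = box(cx - 0.11 * w, y_top, cx + 0.11 * w, y_bot)
    dorsal = [_ellipse(cx + s * 0.10 * w, 0.25 * h, 0.16 * w, 0.18 * h) for s in (-1, 1)]
    ventral = [_ellipse(cx + s * 0.10 * w, 0.55 * h, 0.34 * w, 0.30 * h) for s in (-1, 1)]
    outline = _as_single_polygon(unary_union([column, *dorsal, *ventral]), "grey outline")

    band_h = (y_bot - y_top) / n_laminae
    boundaries = [y_top + k * band_h for k in range(n_laminae + 1)]

    # Nuclei are small discs centred on laminar boundaries so that
    # subtracting them notches the neighbouring bands without creating
    # holes.  Lateral positions keep them pairwise disjoint.
    radius = min(0.025 * w, 0.35 * band_h)
    idx_d = int(np.clip(round(0.45 * n_laminae), 1, n_laminae - 1))
    idx_i = int(np.clip(idx_d + 1, 1, n_laminae - 1))
    idx_l = int(np.clip(round(0.75 * n_laminae), 1, n_laminae - 1))
    if idx_l == idx_i:
        idx_l = min(idx_i + 1, n_laminae - 1)
    nucleus_centres = {
        "D": (cx, boundaries[idx_d]),
        "ICI": (cx - 0.08 * w, boundaries[idx_i]),
        "IMM": (cx + 0.08 * w, boundaries[idx_i]),
        "IML": (cx - 0.28 * w, boundaries[idx_i]),
        "LDCom": (cx, boundaries[idx_l]),
    }
    nuclei: dict[str, Polygon] = {}
    for rid in NUCLEUS_IDS:
        x0, y0 = nucleus_centres[rid]
        disc = Point(x0, y0).buffer(radius, quad_segs=_CIRCLE_SEGMENTS // 4)
        nuclei[rid] = _as_single_polygon(disc.intersection(outline), f"nucleus {rid}")
    all_nuclei = unary_union(list(nuclei.values()))

    regions: list[Region] = []
    for k in range(n_laminae):
        band = box(0.0, boundaries[k], w, boundaries[k + 1])
        lam = outline.intersection(band).difference(all_nuclei)
        poly = _as_single_polygon(lam, f"lamina L{k + 1}")
        regions.append(Region(f"L{k + 1}", _ring(poly)))
    for rid in NUCLEUS_IDS:
        regions.append(Region(rid, _ring(nuclei[rid])))

    return ToyAtlas(tuple(regions), _ring(outline), (w, h))


def points_in_polygon(poly: Polygon, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorised boundary-inclusive point-in-polygon test."""
    return shapely.intersects_xy(poly, np.asarray(x, float), np.asarray(y, float))
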