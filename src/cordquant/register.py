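"""Landmark-based thin-plate-spline registration and region transfer.

Histological sections deform during cutting and mounting, so a rigid
fit to a reference atlas drawing is not enough.  The standard remedy is
a thin-plate spline (TPS): the unique minimum-bending-energy 2-D
interpolant through a set of landmark pairs,

    f(x) = A·[1, x, y]ᵀ + Σᵢ wᵢ U(‖x − xᵢ‖),    U(r) = r² log r²,

with the kernel weights constrained to have no affine component
(Σw = 0, Σw·x = 0).  With zero regularisation the transform passes
exactly through every landmark; a positive smoothing parameter λ trades
landmark fidelity for smoothness.

The default registration direction maps the atlas (moving image) onto
the section, so detections are never deformed; regions of interest
drawn in atlas space are densified and warped vertex-wise into section
space, and detections are then assigned to regions by point-in-polygon
with a deterministic boundary tie-break (first region in atlas order).

All distances are in µm; no internal rescaling is applied (this only
affects conditioning, not the fitted map, for the landmark counts used
here — typically 11 to 53 pairs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .atlas import Region, ToyAtlas
from .detect import DetectionSet

__all__ = [
    "LandmarkPairs",
    "TPSTransform",
    "fit_tps",
    "apply_tps",
    "warp_regions",
    "assign_to_regions",
    "WarpedRegion",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LandmarkPairs:
    """Paired landmark coordinates in fixed (section) and moving (atlas) space."""

    fixed: np.ndarray  # (n, 2) µm
    moving: np.ndarray  # (n, 2) µm
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.fixed, dtype=float)
        m = np.asarray(self.moving, dtype=float)
        if f.ndim != 2 or f.shape[1] != 2 or f.shape != m.shape:
            raise ValueError("fixed and moving must be (n, 2) arrays of equal shape")
        object.__setattr__(self, "fixed", f)
        object.__setattr__(self, "moving", m)

    def __len__(self) -> int:
        return int(self.fixed.shape[0])

    @classmethod
    def from_csv(cls, path) -> "LandmarkPairs":
        """Read the landmark CSV dialect (name, fixed_x, fixed_y, moving_x, moving_y, active)."""
        df = pd.read_csv(path)
        req = {"fixed_x", "fixed_y", "moving_x", "moving_y"}
        if not req.issubset(df.columns):
            raise ValueError(f"landmark CSV must have columns {sorted(req)}")
        if "active" in df.columns:
            df = df[df["active"].astype(bool)]
        names = tuple(df["name"].astype(str)) if "name" in df.columns else None
        return cls(
            fixed=df[["fixed_x", "fixed_y"]].to_numpy(),
            moving=df[["moving_x", "moving_y"]].to_numpy(),
            names=names,
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "name": self.names or [f"lm{i}" for i in range(len(self))],
                "fixed_x": self.fixed[:, 0], "fixed_y": self.fixed[:, 1],
                "moving_x": self.moving[:, 0], "moving_y": self.moving[:, 1],
                "active": True,
            }
        )
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class TPSTransform:
    """Fitted thin-plate-spline map from source space to target space."""

    affine: np.ndarray  # (2, 3): [a0, ax, ay] rows for x' and y'
    kernel_weights: np.ndarray  # (n, 2)
    source_landmarks: np.ndarray  # (n, 2)
    lam: float
    max_residual: float  # max landmark misfit after the fit, µm

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_tps(self, points)


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r² log r², continuously extended with U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


def _duplicates(points: np.ndarray) -> list[tuple[int, int]]:
    dup = []
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            if np.allclose(points[i], points[j], atol=1e-9):
                dup.append((i, j))
    return dup


def fit_tps(
    landmarks: LandmarkPairs,
    lam: float = 0.0,
    direction: Literal["moving_to_fixed", "fixed_to_moving"] = "moving_to_fixed",
) -> TPSTransform:
    """Solve the TPS linear system for one registration direction.

    ``moving_to_fixed`` (default) maps atlas coordinates into section
    coordinates — the direction used to transfer atlas regions onto an
    unwarped section.  With ``lam = 0`` the fitted map interpolates
    every landmark exactly; ``lam > 0`` adds λI to the kernel block
    (standard TPS smoothing), relaxing the interpolation.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if direction == "moving_to_fixed":
        src, dst = landmarks.moving, landmarks.fixed
    elif direction == "fixed_to_moving":
        src, dst = landmarks.fixed, landmarks.moving
    else:
        raise ValueError(f"unknown direction {direction!r}")
    n = len(landmarks)
    if n < 3:
        raise ValueError(f"need at least 3 landmark pairs, got {n}")
    dup = _duplicates(src)
    if dup:
        raise ValueError(f"duplicate source landmarks at index pairs {dup}: singular system")

    P = np.column_stack([np.ones(n), src])  # (n, 3)
    if np.linalg.matrix_rank(P) < 3:
        raise ValueError(
            "collinear landmarks: the affine part is underdetermined "
            f"(all {n} source landmarks lie on one line)"
        )
    d2 = ((src[:, None, :] - src[None, :, :]) ** 2).sum(-1)
    K = _tps_kernel(d2) + lam * np.eye(n)

    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = dst
    sol = np.linalg.solve(A, rhs)
    w = sol[:n]  # (n, 2)
    a = sol[n:]  # (3, 2): rows = [1, x, y] coefficients

    affine = a.T  # (2, 3)
    t = TPSTransform(affine=affine, kernel_weights=w, source_landmarks=src.copy(),
                     lam=float(lam), max_residual=0.0)
    resid = np.abs(apply_tps(t, src) - dst).max() if n else 0.0
    object.__setattr__(t, "max_residual", float(resid))
    return t


def apply_tps(transform: TPSTransform, points: np.ndarray) -> np.ndarray:
    """Evaluate the fitted TPS at an (m, 2) array of points (vectorised)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d2 = ((pts[:, None, :] - transform.source_landmarks[None, :, :]) ** 2).sum(-1)
    U = _tps_kernel(d2)  # (m, n)
    aff = transform.affine @ np.column_stack([np.ones(len(pts)), pts]).T  # (2, m)
    out = aff.T + U @ transform.kernel_weights
    return out if np.asarray(points).ndim == 2 else out[0]


@dataclass(frozen=True)
class WarpedRegion:
    """A region polygon transferred into section space."""

    region_id: str
    vertices: np.ndarray  # (n, 2) µm, section space
    simple: bool  # False when the warp self-intersected the ring

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


def _densify_ring(ring: np.ndarray, max_seg_um: float) -> np.ndarray:
    out = []
    n = len(ring)
    for i in range(n):
        a, b = ring[i], ring[(i + 1) % n]
        seg = np.linalg.norm(b - a)
        k = max(1, int(np.ceil(seg / max_seg_um)))
        for t in range(k):
            out.append(a + (b - a) * (t / k))
    return np.asarray(out)


def warp_regions(
    regions: ToyAtlas | Sequence[Region],
    transform: TPSTransform,
    densify_um: float = 10.0,
) -> list[WarpedRegion]:
    """Map atlas region polygons into section space.

    Every polygon edge is subdivided so no segment exceeds
    ``densify_um`` before vertex-wise mapping, so curved deformations
    are preserved.  A warped ring that self-intersects is flagged
    (``simple=False``) and a warning emitted; counts drawn from flagged
    regions should be treated as low-confidence.
    """
    if densify_um <= 0:
        raise ValueError("densify_um must be positive")
    region_list = list(regions.regions) if isinstance(regions, ToyAtlas) else list(regions)
    out = []
    for region in region_list:
        dense = _densify_ring(np.asarray(region.vertices, dtype=float), densify_um)
        warped = apply_tps(transform, dense)
        simple = Polygon(warped).is_valid
        if not simple:
            warnings.warn(
                f"warped region {region.region_id} self-intersects; flagged low-confidence",
                stacklevel=2,
            )
        out.append(WarpedRegion(region.region_id, warped, simple))
    return out


def assign_to_regions(
    detections: DetectionSet,
    regions: Sequence[WarpedRegion] | Sequence[Region] | ToyAtlas,
) -> np.ndarray:
    """Assign each detection to the first region (in atlas order) covering it.

    Returns an object array of region ids; points inside no region get
    ``"outside"``.  Interior membership uses the even-odd rule; a point
    exactly on a shared boundary goes to the earlier region in the
    sequence, which makes the assignment deterministic.
    """
    import shapely

    region_list = list(regions.regions) if isinstance(regions, ToyAtlas) else list(regions)
    n = len(detections)
    out = np.array(["outside"] * n, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for region in region_list:
        if not unassigned.any():
            break
        poly = region.polygon
        idx = np.flatnonzero(unassigned)
        inside = shapely.intersects_xy(poly, detections.x[idx], detections.y[idx])
        hit = idx[inside]
        out[hit] = region.region_id
        unassigned[hit] = False
    return out
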