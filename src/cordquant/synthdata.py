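"""Synthetic two-channel section generator with known ground truth.

Emulates the statistical structure of NeuN/DAPI-stained spinal cord
cross-sections from a mouse contusion-injury study:

* neurons are placed as a spatial Poisson process per atlas region, with
  per-region densities (neurons/mm²) thinned by an injury survival
  gradient over rostro-caudal distance to the epicenter;
* each neuron is rendered as a bright disc in the neuronal channel with
  a colocalised nuclear disc in the nuclear channel;
* artifacts (autofluorescence, debris) are bright in the neuronal
  channel only, with no nuclear colocalisation;
* a per-section multiplicative staining gain models the large
  section-to-section variation in staining intensity;
* simulated observers miss neurons, add false positives and jitter
  positions, which generates the multi-rater agreement classes the
  consensus stage analyses.

Everything is reproducible from a single integer seed, expanded into
independent per-stage child streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon

from .atlas import ToyAtlas

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ObserverProfile",
    "SectionImage",
    "default_survival_curve",
    "simulate_section",
    "simulate_probability_map",
    "simulate_observer",
    "simulate_cohort",
]

#: injury survival gradient: fraction of control neurons surviving at a
#: given caudal distance (mm) from the epicenter.  Piecewise linear
#: through roughly 2.3% at 0.6 mm, rising ~20 percentage points per
#: 0.2 mm to a 40% plateau at 1.0-1.2 mm.
SURVIVAL_KNOTS_MM = (0.6, 0.8, 1.0, 1.2)
SURVIVAL_KNOTS_FRAC = (0.023, 0.20, 0.40, 0.40)


def default_survival_curve(
    region_scale: Mapping[str, float] | None = None,
) -> Callable[[float | None, str], float]:
    """Survival fraction as a function of (distance_mm, region_id).

    ``distance_mm = None`` denotes an uninjured control section
    (survival 1 everywhere).  Distances outside the knot range are
    clamped to the nearest knot.  ``region_scale`` optionally rescales
    the curve per region (clipped to [0, 1]); the default applies the
    same gradient to every region.
    """
    xs = np.asarray(SURVIVAL_KNOTS_MM)
    ys = np.asarray(SURVIVAL_KNOTS_FRAC)

    def survival(distance_mm: float | None, region_id: str) -> float:
        if distance_mm is None:
            return 1.0
        s = float(np.interp(distance_mm, xs, ys))
        if region_scale is not None:
            s = min(1.0, max(0.0, s * region_scale.get(region_id, 1.0)))
        return s

    return survival


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the section generator.

    densities may be a single neurons/mm² figure applied to every region
    or a per-region map.  Intensities are on a nominal 0-255 scale.
    """

    pixel_size: float = 2.0  # µm per pixel
    densities: float | Mapping[str, float] = 280.0  # neurons / mm²
    soma_radius_mean: float = 5.0  # µm
    soma_radius_sd: float = 0.8  # µm
    soma_radius_min: float = 3.5  # µm, truncation of the radius draw
    survival_curve: Callable[[float | None, str], float] | None = None
    staining_gain_sd: float = 0.2  # sd of log gain (log-normal)
    artifact_rate: float = 5.0  # artifacts / mm² of frame
    artifact_radius_um: tuple[float, float] = (2.5, 5.0)  # uniform range
    noise_sd: float = 4.0  # additive Gaussian noise per channel
    neuron_intensity: float = 180.0
    nucleus_intensity: float = 150.0
    artifact_intensity: float = 180.0
    psf_sigma_px: float = 1.0  # Gaussian PSF applied before noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        dens = self.densities
        vals = dens.values() if isinstance(dens, Mapping) else [dens]
        if any(d < 0 for d in vals):
            raise ValueError("densities must be non-negative")
        for name in ("soma_radius_sd", "staining_gain_sd", "artifact_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.soma_radius_mean <= 0 or self.soma_radius_min <= 0:
            raise ValueError("soma radii must be positive")

    def density_for(self, region_id: str) -> float:
        if isinstance(self.densities, Mapping):
            return float(self.densities.get(region_id, 0.0))
        return float(self.densities)


@dataclass(frozen=True)
class ObserverProfile:
    """Error model of one human analysis pass over a section."""

    sensitivity: float = 0.9  # P(detect a true neuron)
    fp_rate: float = 0.0  # false positives per mm² of grey matter
    jitter_sd: float = 2.0  # µm isotropic localisation noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must lie in [0, 1]")
        if self.fp_rate < 0 or self.jitter_sd < 0:
            raise ValueError("fp_rate and jitter_sd must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """True object lists for one simulated section."""

    x: np.ndarray  # µm, neurons
    y: np.ndarray
    region_id: np.ndarray  # dtype=object / str per neuron
    soma_radius: np.ndarray  # µm
    artifact_x: np.ndarray
    artifact_y: np.ndarray
    artifact_radius: np.ndarray
    condition: str = "control"
    distance_mm: float | None = None
    section_id: str = ""

    def __len__(self) -> int:
        return int(self.x.size)

    @property
    def n_neurons(self) -> int:
        return len(self)

    def region_counts(self) -> dict[str, int]:
        ids, counts = np.unique(self.region_id.astype(str), return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def soma_area_um2(self) -> np.ndarray:
        return np.pi * self.soma_radius**2


@dataclass(frozen=True)
class SectionImage:
    """Two-channel raster (neuronal + nuclear) with physical metadata."""

    neuronal: np.ndarray  # 2-D float32
    nuclear: np.ndarray
    pixel_size: float  # µm / pixel
    section_id: str = ""
    condition: str = "control"
    distance_mm: float | None = None

    def __post_init__(self) -> None:
        if self.neuronal.shape != self.nuclear.shape:
            raise ValueError("channel shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.neuronal.shape

    @property
    def frame_um(self) -> tuple[float, float]:
        h, w = self.neuronal.shape
        return (w * self.pixel_size, h * self.pixel_size)


def _sample_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform rejection sampling of n points inside a polygon."""
    if n == 0:
        return np.empty(0), np.empty(0)
    minx, miny, maxx, maxy = poly.bounds
    xs, ys = [], []
    need = n
    while need > 0:
        m = max(32, int(need / max(poly.area / ((maxx - minx) * (maxy - miny)), 1e-3)))
        cx = rng.uniform(minx, maxx, m)
        cy = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(poly, cx, cy)
        xs.append(cx[keep][:need])
        ys.append(cy[keep][:need])
        need = n - sum(a.size for a in xs)
    return np.concatenate(xs), np.concatenate(ys)


def _paint_discs(
    img: np.ndarray,
    x_um: np.ndarray,
    y_um: np.ndarray,
    r_um: np.ndarray,
    amplitude: float,
    pixel_size: float,
) -> None:
    """Set pixels whose centre falls inside any disc to ``amplitude``.

    Pixel (i, j) covers [j·s, (j+1)·s) × [i·s, (i+1)·s); its centre is
    ((j+0.5)s, (i+0.5)s).
    """
    h, w = img.shape
    s = pixel_size
    for x, y, r in zip(x_um, y_um, r_um):
        j0 = max(int((x - r) / s - 1), 0)
        j1 = min(int((x + r) / s + 2), w)
        i0 = max(int((y - r) / s - 1), 0)
        i1 = min(int((y + r) / s + 2), h)
        if j0 >= j1 or i0 >= i1:
            continue
        jj = (np.arange(j0, j1) + 0.5) * s - x
        ii = (np.arange(i0, i1) + 0.5) * s - y
        mask = ii[:, None] ** 2 + jj[None, :] ** 2 <= r * r
        patch = img[i0:i1, j0:j1]
        patch[mask] = np.maximum(patch[mask], amplitude)


def neuron_mask(truth: GroundTruth, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Boolean raster of pixels inside any true neuron soma disc."""
    m = np.zeros(shape, dtype=np.float32)
    _paint_discs(m, truth.x, truth.y, truth.soma_radius, 1.0, pixel_size)
    return m > 0


def simulate_section(
    atlas: ToyAtlas,
    config: SimulationConfig,
    distance_mm: float | None = None,
    *,
    condition: str | None = None,
    section_id: str = "",
    seed: int | None = None,
) -> tuple[SectionImage, GroundTruth]:
    """Draw one section: ground truth plus rendered two-channel image.

    The neuron count in each region is Poisson with mean
    ``density × area × survival(distance, region)``; ``distance_mm =
    None`` denotes an uninjured control.  The same (atlas, config,
    distance, seed) always yields bit-identical output.
    """
    survival = config.survival_curve or default_survival_curve()
    if condition is None:
        condition = "control" if distance_mm is None else "injury"
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    ss_counts, ss_pos, ss_rad, ss_art, ss_gain, ss_noise = (
        np.random.default_rng(s) for s in root.spawn(6)
    )

    xs, ys, rids, rads = [], [], [], []
    for region in atlas.regions:
        area_mm2 = region.area_um2 / 1e6
        lam = config.density_for(region.region_id) * area_mm2 * survival(
            distance_mm, region.region_id
        )
        n = int(ss_counts.poisson(lam))
        px, py = _sample_in_polygon(region.polygon, n, ss_pos)
        r = ss_rad.normal(config.soma_radius_mean, config.soma_radius_sd, n)
        r = np.clip(r, config.soma_radius_min, None)
        xs.append(px)
        ys.append(py)
        rads.append(r)
        rids.extend([region.region_id] * n)

    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    radius = np.concatenate(rads) if rads else np.empty(0)
    region_id = np.asarray(rids, dtype=object)

    w_um, h_um = atlas.frame_um
    frame_mm2 = w_um * h_um / 1e6
    n_art = int(ss_art.poisson(config.artifact_rate * frame_mm2))
    ax = ss_art.uniform(0.0, w_um, n_art)
    ay = ss_art.uniform(0.0, h_um, n_art)
    ar = ss_art.uniform(*config.artifact_radius_um, n_art)

    truth = GroundTruth(
        x=x, y=y, region_id=region_id, soma_radius=radius,
        artifact_x=ax, artifact_y=ay, artifact_radius=ar,
        condition=condition, distance_mm=distance_mm, section_id=section_id,
    )

    s = config.pixel_size
    shape = (int(round(h_um / s)), int(round(w_um / s)))
    gain = float(np.exp(ss_gain.normal(0.0, config.staining_gain_sd)))
    neuronal = np.zeros(shape, dtype=np.float32)
    nuclear = np.zeros(shape, dtype=np.float32)
    _paint_discs(neuronal, x, y, radius, config.neuron_intensity * gain, s)
    # nuclear stain fills a slightly smaller disc within each soma
    _paint_discs(nuclear, x, y, 0.75 * radius, config.nucleus_intensity * gain, s)
    _paint_discs(neuronal, ax, ay, ar, config.artifact_intensity * gain, s)
    if config.psf_sigma_px > 0:
        neuronal = gaussian_filter(neuronal, config.psf_sigma_px)
        nuclear = gaussian_filter(nuclear, config.psf_sigma_px)
    if config.noise_sd > 0:
        neuronal = neuronal + ss_noise.normal(0.0, config.noise_sd, shape)
        nuclear = nuclear + ss_noise.normal(0.0, config.noise_sd, shape)
    neuronal = np.clip(neuronal, 0.0, None).astype(np.float32)
    nuclear = np.clip(nuclear, 0.0, None).astype(np.float32)

    image = SectionImage(
        neuronal=neuronal, nuclear=nuclear, pixel_size=s,
        section_id=section_id, condition=condition, distance_mm=distance_mm,
    )
    return image, truth


def simulate_probability_map(
    truth: GroundTruth,
    image: SectionImage,
    miscalibration: float = 0.0,
    *,
    seed: int = 0,
) -> np.ndarray:
    """Per-pixel neuron probability raster, as a trained classifier emits.

    With ``miscalibration = 0`` the map is exactly 1 on true soma pixels
    and 0 elsewhere (artifacts included).  Positive miscalibration pulls
    foreground probabilities below 1 and lifts background above 0 by
    half-normal perturbations of that scale, clipped to [0, 1].
    """
    if miscalibration < 0:
        raise ValueError("miscalibration must be non-negative")
    fg = neuron_mask(truth, image.shape, image.pixel_size)
    prob = fg.astype(np.float64)
    if miscalibration > 0:
        rng = np.random.default_rng(seed)
        noise = np.abs(rng.normal(0.0, miscalibration, image.shape))
        prob = np.where(fg, 1.0 - noise, noise)
    return np.clip(prob, 0.0, 1.0)


def simulate_observer(
    truth: GroundTruth,
    atlas: ToyAtlas,
    profile: ObserverProfile,
    *,
    source_id: str | None = None,
):
    """One simulated manual analysis pass over a section.

    Each true neuron is detected independently with probability
    ``sensitivity`` and its reported position jittered isotropically;
    false positives fall uniformly in the grey outline at ``fp_rate``
    per mm².
    """
    from .detect import DetectionSet  # local import to avoid a cycle

    rng = np.random.default_rng(profile.seed)
    n = len(truth)
    hit = rng.random(n) < profile.sensitivity
    x = truth.x[hit] + rng.normal(0.0, profile.jitter_sd, int(hit.sum()))
    y = truth.y[hit] + rng.normal(0.0, profile.jitter_sd, int(hit.sum()))

    outline = atlas.outline_polygon
    n_fp = int(rng.poisson(profile.fp_rate * outline.area / 1e6))
    fx, fy = _sample_in_polygon(outline, n_fp, rng)

    return DetectionSet(
        x=np.concatenate([x, fx]),
        y=np.concatenate([y, fy]),
        area_um2=None,
        source_id=source_id or f"observer-{profile.seed}",
        section_id=truth.section_id,
    )


def simulate_cohort(
    atlas: ToyAtlas,
    config: SimulationConfig,
    design: Sequence[tuple[str, float | None, int]],
    *,
    seed: int | None = None,
) -> list[tuple[SectionImage, GroundTruth]]:
    """Simulate a study cohort from a (condition, distance_mm, n) design.

    Returns one (image, truth) pair per section, with section ids of the
    form ``{condition}-{distance}-{k}`` and per-section child seeds
    derived from the root seed.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    n_total = sum(n for _, _, n in design)
    children = root.spawn(n_total)
    out = []
    i = 0
    for condition, distance_mm, n_sections in design:
        for k in range(n_sections):
            tag = "ctrl" if distance_mm is None else f"{distance_mm:g}mm"
            sid = f"{condition}-{tag}-{k}"
            child_seed = int(children[i].generate_state(1)[0] % (2**31))
            out.append(
                simulate_section(
                    atlas, config, distance_mm,
                    condition=condition, section_id=sid, seed=child_seed,
                )
            )
            i += 1
    return out
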