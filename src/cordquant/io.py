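"""File formats: TIFF sections, Cell Counter XML, region polygons, sidecars.

Dialects
--------
* Sections are two-page TIFFs (page 0 = neuronal channel, page 1 =
  nuclear channel) written with ImageJ-style µm resolution metadata;
  RGB TIFFs are also accepted on read, mapped red → neuronal and
  blue → nuclear (the green channel is ignored with a warning).
* Point annotations use the Cell Counter XML dialect of Fiji's count
  tool (Marker_Data / Marker_Type / Marker with MarkerX/Y in pixel
  units); coordinates are converted to µm as ``x_px × pixel_size``.
  Fractional pixel coordinates are written so round-trips are lossless.
* Region polygons (atlas or warped) travel as GeoJSON FeatureCollections
  with a ``region_id`` property per feature.
* Ground truth and metadata ride in JSON sidecars next to the image.

All CSV output is UTF-8, comma-delimited, dot-decimal, coordinates in
µm with 3 decimals.
"""

from __future__ import annotations

import json
import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .atlas import Region, ToyAtlas
from .detect import DetectionSet
from .synthdata import GroundTruth, SectionImage

__all__ = [
    "write_section",
    "read_section",
    "write_truth",
    "read_truth",
    "write_cellcounter_xml",
    "read_cellcounter_xml",
    "write_detections_csv",
    "read_detections_csv",
    "write_regions_geojson",
    "read_regions_geojson",
    "write_atlas_geojson",
    "read_atlas_geojson",
]


# ---------------------------------------------------------------- sections

def write_section(path, image: SectionImage) -> None:
    """Write a two-page TIFF (neuronal, nuclear) with µm pixel size."""
    path = Path(path)
    res = 1.0 / image.pixel_size  # pixels per µm
    data = np.stack([image.neuronal, image.nuclear]).astype(np.float32)
    tifffile.imwrite(
        path, data, imagej=True, resolution=(res, res), metadata={"unit": "um"},
    )


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    try:
        xres = page.tags["XResolution"].value
    except KeyError:
        return None
    num, den = (xres if isinstance(xres, tuple) else (xres, 1))
    if num == 0:
        return None
    ppu = num / den  # pixels per unit
    unit = "um" if (tif.imagej_metadata or {}).get("unit") in ("um", "micron") else None
    if unit is None:
        resunit = page.tags.get("ResolutionUnit")
        if resunit is not None and getattr(resunit.value, "name", "") == "CENTIMETER":
            return 1e4 / ppu
        return None
    return 1.0 / ppu


def read_section(
    path,
    pixel_size: float | None = None,
    *,
    section_id: str = "",
    condition: str = "control",
    distance_mm: float | None = None,
) -> SectionImage:
    """Read a section TIFF: 2-page multichannel, or RGB (red/blue used).

    Pixel size comes from the TIFF resolution metadata unless
    overridden; a file without resolution metadata and no override is
    an error.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        tag_px = _pixel_size_from_tiff(tif)
    s = pixel_size if pixel_size is not None else tag_px
    if s is None:
        raise ValueError(f"{path}: no resolution metadata; pass pixel_size explicitly")

    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] not in (2,):
        warnings.warn(f"{path}: RGB input, green channel ignored", stacklevel=2)
        neuronal = arr[..., 0].astype(np.float32)
        nuclear = arr[..., 2].astype(np.float32)
    elif arr.ndim == 3 and arr.shape[0] == 2:
        neuronal = arr[0].astype(np.float32)
        nuclear = arr[1].astype(np.float32)
    else:
        raise ValueError(f"{path}: expected a 2-page or RGB TIFF, got shape {arr.shape}")
    return SectionImage(
        neuronal=neuronal, nuclear=nuclear, pixel_size=float(s),
        section_id=section_id or path.stem, condition=condition, distance_mm=distance_mm,
    )


# ------------------------------------------------------------- truth sidecar

def write_truth(path, truth: GroundTruth) -> None:
    payload = {
        "section_id": truth.section_id,
        "condition": truth.condition,
        "distance_mm": truth.distance_mm,
        "neurons": [
            {"x_um": float(x), "y_um": float(y), "region_id": str(r), "soma_radius_um": float(sr)}
            for x, y, r, sr in zip(truth.x, truth.y, truth.region_id, truth.soma_radius)
        ],
        "artifacts": [
            {"x_um": float(x), "y_um": float(y), "radius_um": float(r)}
            for x, y, r in zip(truth.artifact_x, truth.artifact_y, truth.artifact_radius)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    neurons = d.get("neurons", [])
    arts = d.get("artifacts", [])
    return GroundTruth(
        x=np.array([n["x_um"] for n in neurons], dtype=float),
        y=np.array([n["y_um"] for n in neurons], dtype=float),
        region_id=np.array([n["region_id"] for n in neurons], dtype=object),
        soma_radius=np.array([n["soma_radius_um"] for n in neurons], dtype=float),
        artifact_x=np.array([a["x_um"] for a in arts], dtype=float),
        artifact_y=np.array([a["y_um"] for a in arts], dtype=float),
        artifact_radius=np.array([a["radius_um"] for a in arts], dtype=float),
        condition=d.get("condition", "control"),
        distance_mm=d.get("distance_mm"),
        section_id=d.get("section_id", ""),
    )


# --------------------------------------------------------- Cell Counter XML

def write_cellcounter_xml(path, detections: DetectionSet, pixel_size: float) -> None:
    """Write a Cell Counter marker file; coordinates stored in pixels."""
    root = ET.Element("CellCounter_Marker_File")
    props = ET.SubElement(root, "Image_Properties")
    ET.SubElement(props, "Image_Filename").text = detections.section_id or "unknown"
    data = ET.SubElement(root, "Marker_Data")
    mtype = ET.SubElement(data, "Marker_Type")
    ET.SubElement(mtype, "Type").text = "1"
    ET.SubElement(mtype, "Name").text = detections.source_id or "marker"
    for x, y in zip(detections.x, detections.y):
        m = ET.SubElement(mtype, "Marker")
        ET.SubElement(m, "MarkerX").text = repr(float(x) / pixel_size)
        ET.SubElement(m, "MarkerY").text = repr(float(y) / pixel_size)
        ET.SubElement(m, "MarkerZ").text = "1"
    ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)


def read_cellcounter_xml(path, pixel_size: float) -> list[DetectionSet]:
    """Read a Cell Counter marker file into one DetectionSet per marker type.

    Pixel coordinates are converted to µm as ``value × pixel_size``.
    Malformed XML raises with the offending line number.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        line, col = exc.position
        raise ValueError(f"{path}: malformed XML at line {line}, column {col}: {exc}") from exc
    root = tree.getroot()
    name_el = root.find("./Image_Properties/Image_Filename")
    section_id = name_el.text.strip() if name_el is not None and name_el.text else path.stem

    out = []
    for mtype in root.iter("Marker_Type"):
        label_el = mtype.find("Name")
        type_el = mtype.find("Type")
        label = (
            label_el.text.strip() if label_el is not None and label_el.text
            else (type_el.text.strip() if type_el is not None and type_el.text else "marker")
        )
        xs, ys = [], []
        for marker in mtype.iter("Marker"):
            xs.append(float(marker.findtext("MarkerX")) * pixel_size)
            ys.append(float(marker.findtext("MarkerY")) * pixel_size)
        out.append(DetectionSet(x=np.array(xs), y=np.array(ys), source_id=label, section_id=section_id))
    return out


# ----------------------------------------------------------------- CSV forms

def write_detections_csv(path, detections: DetectionSet) -> None:
    df = detections.as_dataframe()
    df["x_um"] = df["x_um"].round(3)
    df["y_um"] = df["y_um"].round(3)
    df.to_csv(path, index=False)


def read_detections_csv(path) -> DetectionSet:
    return DetectionSet.from_dataframe(pd.read_csv(path))


# ------------------------------------------------------------ region GeoJSON

def _feature(region_id: str, vertices: np.ndarray, **props) -> dict:
    ring = [[float(x), float(y)] for x, y in vertices]
    ring.append(ring[0])
    return {
        "type": "Feature",
        "properties": {"region_id": region_id, **props},
        "geometry": {"type": "Polygon", "coordinates": [ring]},
    }


def write_regions_geojson(path, regions, **extra_props) -> None:
    """Write a sequence of Region/WarpedRegion polygons as GeoJSON."""
    feats = []
    for r in regions:
        props = {"simple": bool(getattr(r, "simple", True))}
        feats.append(_feature(r.region_id, np.asarray(r.vertices), **props))
    fc = {"type": "FeatureCollection", "features": feats, "properties": dict(extra_props)}
    Path(path).write_text(json.dumps(fc))


def read_regions_geojson(path) -> list[Region]:
    fc = json.loads(Path(path).read_text())
    out = []
    for feat in fc["features"]:
        ring = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)[:-1]
        out.append(Region(feat["properties"]["region_id"], ring))
    return out


def write_atlas_geojson(path, atlas: ToyAtlas) -> None:
    feats = [_feature(r.region_id, r.vertices) for r in atlas.regions]
    feats.append(_feature("__grey_outline__", atlas.grey_outline))
    fc = {
        "type": "FeatureCollection",
        "features": feats,
        "properties": {"frame_um": list(atlas.frame_um)},
    }
    Path(path).write_text(json.dumps(fc))


def read_atlas_geojson(path) -> ToyAtlas:
    fc = json.loads(Path(path).read_text())
    regions, outline = [], None
    for feat in fc["features"]:
        ring = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)[:-1]
        rid = feat["properties"]["region_id"]
        if rid == "__grey_outline__":
            outline = ring
        else:
            regions.append(Region(rid, ring))
    if outline is None:
        raise ValueError(f"{path}: missing grey outline feature")
    frame = tuple(fc.get("properties", {}).get("frame_um", (0.0, 0.0)))
    return ToyAtlas(tuple(regions), outline, frame)  # type: ignore[arg-type]
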