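"""Cabbage-head radius and volume from the segmented cross-section and depth.

The visible top of a cabbage head projects to a near-circular blob. Its pixel
count gives an equivalent-circle radius r_px; converting r_px to millimetres
needs the camera-to-equator distance H, because pixel footprint grows with
distance. The head is then modelled as a sphere, V = 4/3·π·r³ — the same model
used for the tape-measured ground truth (radius from circumference).

The apex of the head is the nearest in-mask depth; the equator sits one metric
radius below the apex. Apex distance Z₀ and radius couple through the pinhole
model and solve in closed form:

    r_mm = r_px · Z₀ / (f − r_px),   H = Z₀ + r_mm.
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from .errors import (
    CabbageMorphError,
    DegenerateMaskError,
    MissingDepthError,
)
from .io_formats import CameraModel, DepthRaster, InstanceMask
from .leaf_morphometry import HeadMeasure

MM3_PER_M3 = 1e9

#: Percentile of in-mask depths taken as the apex distance; a low percentile
#: rather than the minimum resists depth speckle.
DEFAULT_APEX_PERCENTILE = 5.0


def head_radius_px(head_mask: InstanceMask) -> float:
    """Equivalent-circle radius (pixels) of the segmented head cross-section."""
    area = head_mask.area_px
    if area == 0:
        raise DegenerateMaskError("empty head mask")
    return float(np.sqrt(area / np.pi))


def cross_section_distance(
    head_mask: InstanceMask,
    depth: DepthRaster,
    camera: CameraModel,
    r_px: float,
    apex_percentile: float = DEFAULT_APEX_PERCENTILE,
) -> float:
    """Camera-to-equator distance H (mm) of the head.

    The apex distance Z₀ is a robust minimum (low percentile) of the depths
    inside the head mask; the equator lies one metric radius farther:
    H = Z₀ + r_mm with r_mm = r_px·Z₀/(f − r_px).
    """
    sel = head_mask.raster & depth.valid_mask()
    if not sel.any():
        raise MissingDepthError("no valid depth pixel inside the head mask")
    if r_px >= camera.focal_length:
        raise CabbageMorphError(
            f"r_px = {r_px:.1f} >= focal length {camera.focal_length:.1f}; "
            "object too large for the pinhole model"
        )
    z0 = float(np.percentile(depth.values[sel], apex_percentile))
    r_mm = r_px * z0 / (camera.focal_length - r_px)
    return z0 + r_mm


def px_to_mm(
    r_px: float,
    H: float,
    camera: CameraModel,
    mode: Literal["pinhole", "literal"] = "pinhole",
) -> float:
    """Convert a pixel radius to millimetres at camera distance H.

    Pinhole (default): r_mm = r_px · H / f — the similar-triangles conversion
    with constant k ≡ 1/f. Literal: r_mm = r_px · k / H, an alternative
    reading (division by distance) kept selectable for sensitivity
    experiments; it shrinks distant objects and is not physically meaningful.
    """
    if H <= 0:
        raise CabbageMorphError("camera distance H must be positive")
    k = 1.0 / camera.focal_length
    if mode == "pinhole":
        return r_px * H * k
    if mode == "literal":
        return r_px * k / H
    raise ValueError(f"unknown conversion mode {mode!r}")


def sphere_volume(radius_mm: float) -> float:
    """Sphere volume V = 4/3·π·r³, radius in mm, volume in m³."""
    if radius_mm < 0:
        raise CabbageMorphError("radius must be non-negative")
    return (4.0 / 3.0) * np.pi * radius_mm**3 / MM3_PER_M3


def volume_from_circumference(circumference_mm: float) -> float:
    """Ground-truth helper: sphere volume from a tape-measured circumference."""
    if circumference_mm <= 0:
        raise CabbageMorphError("circumference must be positive")
    return sphere_volume(circumference_mm / (2.0 * np.pi))


def reference_scale(
    reference_mask: InstanceMask,
    known_size_mm: float,
    axis: Literal["width", "height"] = "width",
) -> float:
    """mm-per-pixel scale from a reference object of known physical extent.

    Used when converting scanned ground-truth leaf masks to metric areas:
    one mask pixel covers scale² mm².
    """
    if not reference_mask.raster.any():
        raise DegenerateMaskError("empty reference mask")
    rows, cols = np.nonzero(reference_mask.raster)
    extent = (cols.max() - cols.min() + 1) if axis == "width" else (rows.max() - rows.min() + 1)
    return known_size_mm / float(extent)


def combine_reference_scales(scales: list[float], rel_tol: float = 0.01) -> tuple[float, bool]:
    """Mean of several reference-object scales; flags inconsistency when any
    scale deviates from the mean by more than ``rel_tol`` relatively."""
    arr = np.asarray(scales, dtype=float)
    mean = float(arr.mean())
    consistent = bool(np.all(np.abs(arr - mean) <= rel_tol * mean))
    return mean, consistent


def measure_head(
    head_mask: InstanceMask,
    depth: DepthRaster,
    camera: CameraModel,
    apex_percentile: float = DEFAULT_APEX_PERCENTILE,
    eq_mode: Literal["pinhole", "literal"] = "pinhole",
) -> HeadMeasure:
    """Full head measurement: equivalent-circle radius, metric conversion at
    the equator distance, sphere volume."""
    r_px = head_radius_px(head_mask)
    H = cross_section_distance(head_mask, depth, camera, r_px, apex_percentile)
    r_mm = px_to_mm(r_px, H, camera, mode=eq_mode)
    return HeadMeasure(
        radius_px=r_px,
        radius_mm=r_mm,
        cross_section_distance=H,
        volume=sphere_volume(r_mm),
    )
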