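"""Leaf-to-plant assignment, 3D leaf lengths, and length-based leaf area.

Only leaf length is observable from above (the widest part of an outer cabbage
leaf is hidden under its neighbours), so leaf area is estimated from length
alone by an allometric rule: each leaf's length Lᵢ is multiplied by the
plant-wide mean leaf length L̄ and a shape factor of 2.7 that absorbs the
unobservable width,

    areaᵢ = L̄ · Lᵢ · 2.7        total LA = Σᵢ areaᵢ = 2.7 · n · L̄².

Lengths are straight-line 3D Euclidean distances from the shared attachment
point to each leaf's farthest point; leaf curvature is deliberately ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateCloudError, EmptyPlantError, InvalidMeasureError
from .io_formats import InstanceMask, LeafPointCloud
from .stem_locator import AttachmentPoint

MM2_PER_M2 = 1e6

#: Allometric shape factor replacing the unobservable leaf width.
DEFAULT_SHAPE_FACTOR = 2.7

#: A leaf belongs to a plant when more than this fraction of its area lies
#: inside the plant's mask.
DEFAULT_ASSIGN_THRESHOLD = 0.8


@dataclass(frozen=True)
class LeafMeasure:
    """Per-leaf result: endpoint q, length L (mm), allometric area (m²)."""

    leaf_id: int
    plant_id: int
    endpoint: tuple[float, float, float]
    length: float
    area: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise InvalidMeasureError(f"leaf {self.leaf_id}: non-positive length")
        if self.area <= 0:
            raise InvalidMeasureError(f"leaf {self.leaf_id}: non-positive area")


@dataclass
class HeadMeasure:
    """Cabbage-head result (defined in head_volume; stored on the plant record)."""

    radius_px: float
    radius_mm: float
    cross_section_distance: float
    volume: float


@dataclass
class PlantMeasure:
    """Per-plant result record."""

    plant_id: int
    attachment: AttachmentPoint
    leaves: list[LeafMeasure] = field(default_factory=list)
    mean_leaf_length: float = 0.0  # L̄, mm
    total_leaf_area: float = 0.0  # LA, m²
    head: HeadMeasure | None = None
    warnings: list[str] = field(default_factory=list)


def assign_leaves(
    leaf_masks: Sequence[InstanceMask],
    plant_masks: Sequence[InstanceMask],
    threshold: float = DEFAULT_ASSIGN_THRESHOLD,
) -> dict[int, int | None]:
    """Assign each leaf to the plant containing more than ``threshold`` of it.

    Returns leaf_id -> plant_id (None when no plant exceeds the threshold).
    When several plants exceed it, the largest overlap fraction wins, ties
    going to the lower plant_id.
    """
    out: dict[int, int | None] = {}
    for leaf in leaf_masks:
        area = leaf.area_px
        best: tuple[float, int] | None = None
        for plant in plant_masks:
            frac = np.count_nonzero(leaf.raster & plant.raster) / area
            if frac > threshold:
                # sort key: bigger fraction first, then lower id
                if best is None or (frac, -plant.instance_id) > (best[0], -best[1]):
                    best = (frac, plant.instance_id)
        out[leaf.instance_id] = None if best is None else best[1]
    return out


def leaf_endpoint(cloud: LeafPointCloud, p: AttachmentPoint) -> np.ndarray:
    """Leaf endpoint q: the cloud point farthest (3D Euclidean) from p.

    Ties resolve to the first occurrence in scan order (np.argmax).
    """
    if len(cloud) == 0:  # cannot happen for a valid LeafPointCloud, kept defensive
        raise DegenerateCloudError(f"leaf {cloud.leaf_id}: empty cloud")
    d2 = np.sum((cloud.points - p.xyz) ** 2, axis=1)
    return cloud.points[int(np.argmax(d2))]


def leaf_length(p: AttachmentPoint, q: np.ndarray) -> float:
    """Straight-line 3D distance (mm) from attachment point p to endpoint q."""
    return float(np.linalg.norm(np.asarray(q, dtype=float) - p.xyz))


def leaf_areas(
    lengths: Sequence[float],
    shape_factor: float = DEFAULT_SHAPE_FACTOR,
) -> tuple[np.ndarray, float]:
    """Allometric per-leaf areas (m²) and their total from leaf lengths (mm).

    areaᵢ = L̄ · Lᵢ · shape_factor with L̄ the mean length, converted mm² → m²;
    the total satisfies the closed form shape_factor · n · L̄².
    """
    L = np.asarray(lengths, dtype=float)
    if L.size == 0:
        raise EmptyPlantError("no leaf lengths supplied")
    if np.any(L <= 0):
        raise InvalidMeasureError("leaf lengths must be positive")
    areas = L.mean() * L * shape_factor / MM2_PER_M2
    return areas, float(areas.sum())


def measure_plant_leaves(
    leaf_clouds: Sequence[LeafPointCloud],
    attachment: AttachmentPoint,
    plant_id: int = 0,
    shape_factor: float = DEFAULT_SHAPE_FACTOR,
) -> PlantMeasure:
    """Endpoint, length and area for every leaf of one plant, plus totals."""
    if len(leaf_clouds) == 0:
        raise EmptyPlantError(f"plant {plant_id} has no leaf clouds")
    endpoints = [leaf_endpoint(c, attachment) for c in leaf_clouds]
    lengths = [leaf_length(attachment, q) for q in endpoints]
    areas, total = leaf_areas(lengths, shape_factor)
    leaves = [
        LeafMeasure(
            leaf_id=c.leaf_id,
            plant_id=plant_id,
            endpoint=(float(q[0]), float(q[1]), float(q[2])),
            length=length,
            area=float(area),
        )
        for c, q, length, area in zip(leaf_clouds, endpoints, lengths, areas)
    ]
    return PlantMeasure(
        plant_id=plant_id,
        attachment=attachment,
        leaves=leaves,
        mean_leaf_length=float(np.mean(lengths)),
        total_leaf_area=total,
    )
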