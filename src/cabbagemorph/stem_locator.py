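"""Leaf-attachment point estimation from per-leaf plane intersections.

The stem of a cabbage is hidden under the canopy, but every leaf converges at
it: extending each leaf's fitted plane inward, planes of different leaves meet
near the stem. Three planes in general position meet in a single point, so all
unordered plane triples are solved; solutions that project into the segmented
plant area and lie at a plausible height are averaged into the attachment
point estimate p.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np

from .errors import InsufficientPlanesError, NoSupportError
from .io_formats import (
    CameraModel,
    DepthRaster,
    InstanceMask,
    LeafPointCloud,
    project,
)
from .robust_plane import MsacConfig, Plane, fit_leaf_plane


@dataclass(frozen=True)
class AttachmentPoint:
    """Estimated 3D leaf-attachment point with its supporting evidence."""

    position: tuple[float, float, float]  # mm, world frame
    support: int  # intersection points averaged
    dispersion: float  # RMS distance (mm) of those points from position

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be at least 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass(frozen=True)
class StemConfig:
    """Filters applied to raw triple-intersection points.

    det_threshold: minimum |det| of the row-normalised 3x3 system; near-parallel
    plane triples otherwise generate wild far-away intersections.
    z bounds: physical plausibility window; None for z_max means camera height.
    aggregate: mean reproduces the averaging definition of p; median available
    for robustness experiments.
    """

    det_threshold: float = 1e-6
    z_min: float = 0.0
    z_max: float | None = None  # None -> camera_height
    aggregate: Literal["mean", "median"] = "mean"


def _solve_triple(planes: Sequence[Plane], det_threshold: float) -> np.ndarray | None:
    """Intersection point of 3 graph-form planes, or None when ill-conditioned.

    System: aᵢ·x + bᵢ·y − z = −cᵢ. Conditioning is judged on the determinant
    after normalising each row to unit length so the test is scale-free.
    """
    A = np.array([[p.a, p.b, -1.0] for p in planes])
    rhs = np.array([-p.c for p in planes])
    norms = np.linalg.norm(A, axis=1, keepdims=True)
    if abs(np.linalg.det(A / norms)) < det_threshold:
        return None
    return np.linalg.solve(A, rhs)


def triple_intersections(
    planes: Sequence[Plane],
    plant_mask: InstanceMask | None,
    depth: DepthRaster | None,
    camera: CameraModel,
    config: StemConfig | None = None,
) -> list[np.ndarray]:
    """Solve every unordered plane triple and keep plausible intersection points.

    A point survives when (i) the triple's 3x3 system is well conditioned,
    (ii) its projection falls inside the plant mask (skipped when plant_mask is
    None, e.g. in synthetic equivariance tests), and (iii) its height lies in
    the configured plausibility window.
    """
    config = config or StemConfig()
    if len(planes) < 3:
        raise InsufficientPlanesError(
            f"need at least 3 leaf planes, got {len(planes)}"
        )
    z_max = camera.camera_height if config.z_max is None else config.z_max

    points: list[np.ndarray] = []
    for trio in combinations(planes, 3):
        pt = _solve_triple(trio, config.det_threshold)
        if pt is None:
            continue
        if not (config.z_min <= pt[2] <= z_max):
            continue
        if plant_mask is not None:
            col, row = project(pt, camera)
            c, r = int(round(float(col[0]))), int(round(float(row[0])))
            h, w = plant_mask.raster.shape
            if not (0 <= r < h and 0 <= c < w) or not plant_mask.raster[r, c]:
                continue
        points.append(pt)
    if not points:
        raise NoSupportError("no plane-triple intersection survived filtering")
    return points


def attachment_point(
    intersections: Sequence[np.ndarray],
    aggregate: Literal["mean", "median"] = "mean",
) -> AttachmentPoint:
    """Aggregate intersection points into the attachment-point estimate."""
    if len(intersections) == 0:
        raise NoSupportError("empty intersection list")
    pts = np.asarray(intersections, dtype=float)
    if aggregate == "mean":
        pos = pts.mean(axis=0)
    elif aggregate == "median":
        pos = np.median(pts, axis=0)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    rms = float(np.sqrt(np.mean(np.sum((pts - pos) ** 2, axis=1))))
    return AttachmentPoint(
        position=(float(pos[0]), float(pos[1]), float(pos[2])),
        support=len(pts),
        dispersion=rms,
    )


def locate_stem(
    leaf_clouds: Sequence[LeafPointCloud],
    plant_mask: InstanceMask | None,
    depth: DepthRaster | None,
    camera: CameraModel,
    msac_config: MsacConfig | None = None,
    stem_config: StemConfig | None = None,
) -> AttachmentPoint:
    """Full stem localisation: per-leaf MSAC + regression plane, then the
    filtered triple-intersection average. Leaves whose plane fit fails
    (degenerate geometry) are dropped; fewer than 3 usable planes is an error.
    """
    stem_config = stem_config or StemConfig()
    if len(leaf_clouds) < 3:
        raise InsufficientPlanesError(
            f"plant has {len(leaf_clouds)} usable leaves; need at least 3"
        )
    planes: list[Plane] = []
    for cloud in leaf_clouds:
        try:
            plane, _ = fit_leaf_plane(cloud, msac_config)
        except Exception:
            continue
        planes.append(plane)
    if len(planes) < 3:
        raise InsufficientPlanesError(
            f"only {len(planes)} of {len(leaf_clouds)} leaves produced a plane"
        )
    pts = triple_intersections(planes, plant_mask, depth, camera, stem_config)
    return attachment_point(pts, aggregate=stem_config.aggregate)
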