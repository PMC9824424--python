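"""Readers, writers and geometric back-projection for the pipeline's external formats.

Conventions used throughout the package:

* Image frame: 0-based, origin top-left, coordinates given as (col, row).
* World frame: z = 0 on the ground plane, z up, x along +col, y along +row,
  origin on the camera's optical axis.
* Depth rasters store camera-to-surface distance in millimetres along the
  optical axis (what SfM/MVS depth maps produce), not surface height; surface
  height is ``camera_height - depth``.
* Stored 0 in integer depth rasters is the no-data sentinel.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from PIL import Image
from skimage.draw import polygon as draw_polygon

from .errors import (
    DegenerateCloudError,
    FormatError,
    MappingError,
)

ClassLabel = Literal["plant", "head", "leaf"]

#: Mapping from common annotation category names to the package's three classes.
#: "crop" is the field name some datasets use for the cabbage head.
DEFAULT_CATEGORY_MAP: dict[str, ClassLabel] = {
    "plant": "plant",
    "head": "head",
    "crop": "head",
    "leaf": "leaf",
}


@dataclass(frozen=True)
class CameraModel:
    """Nadir pinhole camera over a flat field.

    Parameters
    ----------
    focal_length
        Focal length in pixels. Also fixes the pixel-to-metric conversion
        constant: at camera-to-surface distance H mm, one pixel spans
        ``H / focal_length`` mm.
    principal_point
        (col, row) of the optical axis in the image.
    camera_height
        Height of the projection centre above the ground plane, mm.
        Default 900 mm, a typical boom/rover mounting height for nadir
        canopy imaging.
    image_size
        (width, height) in pixels.
    """

    focal_length: float
    principal_point: tuple[float, float]
    camera_height: float = 900.0
    image_size: tuple[int, int] = (1024, 1024)

    def __post_init__(self) -> None:
        if self.focal_length <= 0:
            raise ValueError("focal_length must be positive")
        if self.camera_height <= 0:
            raise ValueError("camera_height must be positive")
        cx, cy = self.principal_point
        w, h = self.image_size
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError("principal_point must lie inside the image bounds")

    @property
    def ground_sampling(self) -> float:
        """Metric extent (mm) of one pixel on the ground plane."""
        return self.camera_height / self.focal_length


@dataclass
class DepthRaster:
    """Per-pixel camera-to-surface distance in millimetres."""

    values: np.ndarray  # float64, H x W
    invalid_sentinel: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        valid = self.valid_mask()
        if not np.all(np.isfinite(self.values[valid])):
            raise ValueError("non-sentinel depth values must be finite")
        if np.any(self.values[valid] <= 0):
            raise ValueError("non-sentinel depth values must be positive")

    def valid_mask(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.isfinite(self.values) & (self.values != self.invalid_sentinel)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class InstanceMask:
    """One binary instance mask with its class label and id."""

    raster: np.ndarray  # bool, H x W
    class_label: ClassLabel
    instance_id: int
    score: float | None = None

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=bool)
        if not self.raster.any():
            raise ValueError("InstanceMask must contain at least one true pixel")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")

    @property
    def area_px(self) -> int:
        return int(self.raster.sum())


@dataclass
class LeafPointCloud:
    """Back-projected 3D points of one leaf, world frame, millimetres."""

    points: np.ndarray  # N x 3 float64
    leaf_id: int
    plant_id: int | None = None
    low_support: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 3 or self.points.shape[1] != 3:
            raise DegenerateCloudError(
                f"leaf {self.leaf_id}: need at least 3 finite 3D points, "
                f"got shape {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise DegenerateCloudError(f"leaf {self.leaf_id}: non-finite coordinates")

    def __len__(self) -> int:
        return self.points.shape[0]


# ---------------------------------------------------------------------------
# Label maps
# ---------------------------------------------------------------------------

def read_label_map(path: str | Path, class_label: ClassLabel) -> list[InstanceMask]:
    """Read a single-channel integer label map: 0 = background, each positive
    value one instance. Returns one mask per distinct positive value, ids kept."""
    img = Image.open(path)
    if len(img.getbands()) != 1:
        raise FormatError(f"{path}: label map must be single-channel, got {img.mode}")
    arr = np.asarray(img)
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: label map must be integer-valued, got {arr.dtype}")
    return masks_from_label_array(arr, class_label)


def masks_from_label_array(arr: np.ndarray, class_label: ClassLabel) -> list[InstanceMask]:
    """Split an integer label array into per-instance binary masks."""
    arr = np.asarray(arr)
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"label array must be integer-valued, got {arr.dtype}")
    ids = np.unique(arr)
    return [
        InstanceMask(raster=arr == i, class_label=class_label, instance_id=int(i))
        for i in ids
        if i > 0
    ]


def label_array_from_masks(masks: Sequence[InstanceMask], shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`masks_from_label_array` for non-overlapping masks."""
    out = np.zeros(shape, dtype=np.int32)
    for m in masks:
        out[m.raster] = m.instance_id
    return out


def write_label_map(masks: Sequence[InstanceMask], shape: tuple[int, int], path: str | Path) -> None:
    arr = label_array_from_masks(masks, shape)
    if arr.max() > 65535:
        raise FormatError("instance ids exceed 16-bit PNG range")
    Image.fromarray(arr.astype(np.uint16 if arr.max() > 255 else np.uint8)).save(path)


# ---------------------------------------------------------------------------
# COCO-style annotations
# ---------------------------------------------------------------------------

def _decode_rle(rle: Mapping, shape: tuple[int, int]) -> np.ndarray:
    """Decode COCO uncompressed RLE (column-major, counts alternate 0/1 runs)."""
    counts = rle["counts"]
    if isinstance(counts, (bytes, str)):
        raise FormatError("compressed RLE is not supported; use uncompressed counts")
    h, w = shape
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for run in counts:
        flat[pos : pos + run] = val
        pos += run
        val = not val
    if pos != h * w:
        raise FormatError(f"RLE counts sum to {pos}, expected {h * w}")
    return flat.reshape((w, h)).T  # column-major


def _encode_rle(mask: np.ndarray) -> dict:
    """Encode a binary mask as COCO uncompressed RLE (column-major)."""
    flat = np.asarray(mask, dtype=bool).T.ravel()
    # run boundaries; COCO counts always start with a zero-run
    change = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    counts = np.diff(bounds).tolist()
    if flat[0]:
        counts = [0] + counts
    return {"counts": counts, "size": [mask.shape[0], mask.shape[1]]}


def _rasterize_polygon(coords: Sequence[float], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize one COCO polygon ring given as a flat [x0,y0,x1,y1,...] list.

    Pixel-center semantics: a pixel is foreground when its center lies inside
    the polygon, which keeps the mask area close to the shoelace area.
    """
    from skimage.measure import grid_points_in_poly

    xy = np.asarray(coords, dtype=float).reshape(-1, 2)
    return grid_points_in_poly(shape, np.column_stack([xy[:, 1], xy[:, 0]]))


def read_coco_annotations(
    path: str | Path,
    category_map: Mapping[str, ClassLabel] | None = None,
) -> dict[int, list[InstanceMask]]:
    """Read a COCO instance-annotation file; returns masks grouped by image id.

    Polygon segmentations are rasterized to the image size; uncompressed RLE is
    decoded directly. Category names are mapped onto {plant, head, leaf}
    ("crop" is accepted as a synonym for the head).
    """
    cat_map = dict(DEFAULT_CATEGORY_MAP if category_map is None else category_map)
    with open(path) as fh:
        doc = json.load(fh)

    cat_label: dict[int, ClassLabel] = {}
    for cat in doc.get("categories", []):
        name = cat["name"].lower()
        if name not in cat_map:
            raise MappingError(
                f"unknown category name {cat['name']!r}; expected one of {sorted(cat_map)}"
            )
        cat_label[cat["id"]] = cat_map[name]

    img_shape = {
        img["id"]: (img["height"], img["width"]) for img in doc.get("images", [])
    }

    out: dict[int, list[InstanceMask]] = {img_id: [] for img_id in img_shape}
    for ann in doc.get("annotations", []):
        shape = img_shape[ann["image_id"]]
        seg = ann["segmentation"]
        if isinstance(seg, Mapping):  # RLE
            mask = _decode_rle(seg, shape)
        else:  # list of polygon rings
            mask = np.zeros(shape, dtype=bool)
            for ring in seg:
                mask |= _rasterize_polygon(ring, shape)
        out.setdefault(ann["image_id"], []).append(
            InstanceMask(
                raster=mask,
                class_label=cat_label[ann["category_id"]],
                instance_id=int(ann["id"]),
                score=ann.get("score"),
            )
        )
    return out


def write_coco_annotations(
    masks_by_image: Mapping[int, Sequence[InstanceMask]],
    image_shapes: Mapping[int, tuple[int, int]],
    path: str | Path,
) -> None:
    """Write masks as a COCO instance file with uncompressed RLE segmentations."""
    categories = [
        {"id": 1, "name": "plant"},
        {"id": 2, "name": "head"},
        {"id": 3, "name": "leaf"},
    ]
    cat_id = {"plant": 1, "head": 2, "leaf": 3}
    images = [
        {"id": img_id, "height": h, "width": w}
        for img_id, (h, w) in image_shapes.items()
    ]
    annotations = []
    for img_id, masks in masks_by_image.items():
        for m in masks:
            ann = {
                "id": m.instance_id,
                "image_id": img_id,
                "category_id": cat_id[m.class_label],
                "segmentation": _encode_rle(m.raster),
                "area": m.area_px,
            }
            if m.score is not None:
                ann["score"] = m.score
            annotations.append(ann)
    with open(path, "w") as fh:
        json.dump(
            {"images": images, "categories": categories, "annotations": annotations},
            fh,
        )


# ---------------------------------------------------------------------------
# Depth rasters
# ---------------------------------------------------------------------------

def read_depth_raster(path: str | Path, unit_scale: float = 1.0) -> DepthRaster:
    """Read a single-channel depth raster and convert stored units to mm.

    16-bit integer PNGs use stored 0 as the no-data sentinel; float TIFFs use
    NaN or 0. Negative stored values are a format error.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        img = Image.open(path)
        if len(img.getbands()) != 1:
            raise FormatError(f"{path}: depth raster must be single-channel")
        arr = np.asarray(img)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise FormatError(f"{path}: depth raster must be 2-D, got shape {arr.shape}")
    if np.any(arr[np.isfinite(arr)] < 0):
        raise FormatError(f"{path}: negative depth values")
    nodata = ~np.isfinite(arr) | (arr == 0)
    values = arr * unit_scale
    values[nodata] = 0.0
    return DepthRaster(values=values, invalid_sentinel=0.0)


def write_depth_raster(depth: DepthRaster, path: str | Path, unit_scale: float = 1.0) -> None:
    """Write depth as 16-bit PNG (stored = mm / unit_scale, sentinel 0)."""
    stored = depth.values / unit_scale
    stored[~depth.valid_mask()] = 0
    if stored.max() > 65535:
        raise FormatError("depth exceeds 16-bit range at this unit_scale")
    Image.fromarray(np.round(stored).astype(np.uint16)).save(path)


# ---------------------------------------------------------------------------
# Back-projection
# ---------------------------------------------------------------------------

def backproject(
    mask: InstanceMask,
    depth: DepthRaster,
    camera: CameraModel,
    mode: Literal["perspective", "orthographic"] = "perspective",
) -> LeafPointCloud:
    """Lift the depth pixels under a mask into world-frame 3D points.

    Perspective (default): a pixel (col, row) at depth d maps to
    ``x = (col - cx) d / f``, ``y = (row - cy) d / f``, ``z = camera_height - d``.
    Orthographic: x, y are scaled pixel offsets at the ground sampling distance,
    for analytically simple test scenes.
    """
    if mask.raster.shape != depth.shape:
        raise FormatError(
            f"mask shape {mask.raster.shape} does not match depth shape {depth.shape}"
        )
    rows, cols = np.nonzero(mask.raster & depth.valid_mask())
    if rows.size < 3:
        raise DegenerateCloudError(
            f"instance {mask.instance_id}: only {rows.size} valid depth pixels"
        )
    d = depth.values[rows, cols]
    cx, cy = camera.principal_point
    if mode == "perspective":
        x = (cols - cx) * d / camera.focal_length
        y = (rows - cy) * d / camera.focal_length
    elif mode == "orthographic":
        g = camera.ground_sampling
        x = (cols - cx) * g
        y = (rows - cy) * g
    else:
        raise ValueError(f"unknown projection mode {mode!r}")
    z = camera.camera_height - d
    return LeafPointCloud(
        points=np.column_stack([x, y, z]), leaf_id=mask.instance_id
    )


def project(
    points: np.ndarray, camera: CameraModel
) -> tuple[np.ndarray, np.ndarray]:
    """Forward pinhole projection of world points to (col, row) pixel coordinates."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = camera.camera_height - pts[:, 2]
    cx, cy = camera.principal_point
    with np.errstate(divide="ignore", invalid="ignore"):
        col = cx + camera.focal_length * pts[:, 0] / d
        row = cy + camera.focal_length * pts[:, 1] / d
    return col, row


# ---------------------------------------------------------------------------
# Point clouds and result tables
# ---------------------------------------------------------------------------

def write_ply(cloud: LeafPointCloud, path: str | Path) -> None:
    """Write an ASCII PLY vertex list (x y z per vertex, float)."""
    pts = cloud.points
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(pts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        for x, y, z in pts:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


def read_ply(path: str | Path, leaf_id: int = 0) -> LeafPointCloud:
    """Read an ASCII PLY vertex list written by :func:`write_ply`."""
    with open(path) as fh:
        header = []
        for line in fh:
            header.append(line.strip())
            if line.strip() == "end_header":
                break
        n = next(
            int(h.split()[-1]) for h in header if h.startswith("element vertex")
        )
        pts = np.loadtxt(fh, max_rows=n, ndmin=2)
    return LeafPointCloud(points=pts[:, :3], leaf_id=leaf_id)


MEASURE_COLUMNS = [
    "plant_id",
    "leaf_id",
    "length_mm",
    "area_m2",
    "head_radius_mm",
    "head_volume_m3",
]


def write_measures(rows: Iterable[Mapping], path: str | Path) -> None:
    """Write measurement rows (one per plant and one per leaf) as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MEASURE_COLUMNS, restval="")
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in MEASURE_COLUMNS})


def read_measures(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return [dict(r) for r in csv.DictReader(fh)]
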