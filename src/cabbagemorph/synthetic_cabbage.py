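"""Parametric top-down cabbage-scene generator with exact ground truth.

Scenes emulate nadir imagery of row-grown cabbage: each plant carries 10-25
planar elliptical leaves radiating funnel-like from a hidden stem attachment
point, optionally plus a spherical head tangent to that point (head absent in
the earliest growth stage). Rendering is a z-buffer rasterization under the
pinhole model producing a depth raster (camera-to-surface distance, mm) and
per-class instance label maps, with optional Gaussian depth noise and uniform
outlier pixels. The generator records exact truth — attachment point, per-leaf
length/width/area/occlusion, head radius and volume — so every pipeline stage
can be tested for parameter recovery.

Leaves are planar because the measurement model itself ignores leaf curvature;
planar truth makes length recovery exactly testable. A cylindrical-bend flag
exists for robustness experiments only.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import CabbageMorphError, LayoutError
from .head_volume import sphere_volume
from .io_formats import CameraModel, DepthRaster, InstanceMask, masks_from_label_array


def default_camera(image_size: tuple[int, int] = (1024, 1024)) -> CameraModel:
    """Nadir camera at 900 mm with a 1000 px focal length (≈0.9 mm ground sampling)."""
    w, h = image_size
    return CameraModel(
        focal_length=1000.0,
        principal_point=(w / 2.0, h / 2.0),
        camera_height=900.0,
        image_size=image_size,
    )


@dataclass
class PlantSpec:
    """Specification of one synthetic plant.

    leaf_lengths / leaf_widths: explicit per-leaf values, or a (min, max)
    tuple sampled uniformly. Elevation angle is the funnel steepness (degrees
    above horizontal); azimuths are equally spaced with uniform jitter.
    head_radius None reproduces the pre-heading growth stage.
    """

    stem_xy: tuple[float, float] = (0.0, 0.0)
    attachment_z: float = 80.0
    n_leaves: int = 12
    leaf_lengths: Sequence[float] | tuple[float, float] = (150.0, 350.0)
    leaf_widths: Sequence[float] | tuple[float, float] | None = None
    elevation_angle: float = 25.0
    azimuth_jitter: float = 5.0
    head_radius: float | None = None
    curvature: float = 0.0  # cylindrical bend, robustness experiments only

    def __post_init__(self) -> None:
        if self.n_leaves < 3:
            raise ValueError("stem recovery needs at least 3 leaves")
        if self.head_radius is not None and self.head_radius < 0:
            raise ValueError("head_radius must be non-negative")

    @property
    def head_center_z(self) -> float | None:
        """Sphere tangent to the attachment point from above."""
        if self.head_radius is None:
            return None
        return self.attachment_z + self.head_radius


@dataclass
class LeafPatch:
    """Planar elliptical leaf surface: center, in-plane axes, semi-axes (mm)."""

    leaf_id: int
    plant_id: int
    center: np.ndarray  # (3,)
    axis_u: np.ndarray  # unit, along the length
    axis_w: np.ndarray  # unit, along the width
    semi_len: float
    semi_wid: float
    is_occluder: bool = False
    curvature: float = 0.0

    @property
    def tip(self) -> np.ndarray:
        """Inner tip (touches the attachment point for true leaves)."""
        return self.center - self.semi_len * self.axis_u

    @property
    def plane(self) -> tuple[float, float, float]:
        """Graph-form coefficients (a, b, c) of the leaf plane z = a·x+b·y+c."""
        n = np.cross(self.axis_u, self.axis_w)
        a = -n[0] / n[2]
        b = -n[1] / n[2]
        c = self.center[2] - a * self.center[0] - b * self.center[1]
        return float(a), float(b), float(c)

    @property
    def true_length(self) -> float:
        return 2.0 * self.semi_len

    @property
    def true_area_m2(self) -> float:
        """Exact ellipse area π·(L/2)·(W/2), m²."""
        return float(np.pi * self.semi_len * self.semi_wid) / 1e6


@dataclass
class HeadBall:
    plant_id: int
    center: np.ndarray  # (3,)
    radius: float


@dataclass
class LeafTruth:
    leaf_id: int
    plant_id: int
    length: float
    width: float
    area_m2: float
    occlusion: float = 0.0
    is_occluder: bool = False


@dataclass
class PlantTruth:
    plant_id: int
    attachment: np.ndarray  # (3,)
    leaves: list[LeafTruth]
    head_radius: float | None = None
    head_volume: float | None = None
    low_head_visibility: bool = False

    @property
    def total_leaf_area_m2(self) -> float:
        return sum(lf.area_m2 for lf in self.leaves if not lf.is_occluder)


@dataclass
class SceneGroundTruth:
    """Complete synthetic-scene record: geometry, truth, and noise-free render."""

    camera: CameraModel
    plants: list[PlantTruth]
    patches: list[LeafPatch] = field(repr=False, default_factory=list)
    heads: list[HeadBall] = field(repr=False, default_factory=list)
    depth_true: np.ndarray | None = field(repr=False, default=None)
    label_maps: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def masks(self, class_label: str) -> list[InstanceMask]:
        """Instance masks of one label map.

        ``head_amodal`` is the annotator-style full head silhouette (outline
        estimated through occluding leaves); ``head`` is the visible part only.
        """
        cls = "head" if class_label == "head_amodal" else class_label
        return masks_from_label_array(self.label_maps[class_label], cls)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

def _resolve(values, n, rng, default_ratio=None, lengths=None):
    if values is None:
        return np.asarray(lengths) * default_ratio
    arr = np.asarray(values, dtype=float)
    if arr.shape == (2,) and n != 2:
        return rng.uniform(arr[0], arr[1], size=n)
    if arr.size == n:
        return arr
    if arr.shape == (2,) and n == 2:  # ambiguous; treat as explicit values
        return arr
    raise ValueError(f"expected {n} values or a (min, max) range, got {values!r}")


MIN_STEM_SPACING = 200.0  # mm; cabbage is planted far coarser than this


def build_scene(
    specs: Sequence[PlantSpec],
    camera: CameraModel | None = None,
    seed: int = 0,
) -> SceneGroundTruth:
    """Instantiate plant geometry and render the noise-free scene.

    Deterministic given (specs, camera, seed): leaf lengths/widths drawn from
    their stated laws, azimuths equally spaced plus jitter, heads tangent to
    the attachment point. Raises LayoutError for stems closer than the minimum
    spacing.
    """
    camera = camera or default_camera()
    rng = np.random.default_rng(seed)

    for i, s1 in enumerate(specs):
        for s2 in specs[i + 1 :]:
            d = np.hypot(s1.stem_xy[0] - s2.stem_xy[0], s1.stem_xy[1] - s2.stem_xy[1])
            if d < MIN_STEM_SPACING:
                raise LayoutError(f"stems {d:.0f} mm apart; minimum {MIN_STEM_SPACING} mm")

    patches: list[LeafPatch] = []
    heads: list[HeadBall] = []
    plants: list[PlantTruth] = []
    next_leaf_id = 1
    for plant_id, spec in enumerate(specs, start=1):
        p = np.array([spec.stem_xy[0], spec.stem_xy[1], spec.attachment_z])
        n = spec.n_leaves
        lengths = _resolve(spec.leaf_lengths, n, rng)
        widths = _resolve(spec.leaf_widths, n, rng, default_ratio=0.5, lengths=lengths)
        alpha = np.deg2rad(spec.elevation_angle)
        base_az = np.arange(n) * 2 * np.pi / n
        az = base_az + np.deg2rad(rng.uniform(-spec.azimuth_jitter, spec.azimuth_jitter, size=n))

        leaf_truths = []
        for k in range(n):
            u = np.array(
                [np.cos(az[k]) * np.cos(alpha), np.sin(az[k]) * np.cos(alpha), np.sin(alpha)]
            )
            w = np.array([-np.sin(az[k]), np.cos(az[k]), 0.0])
            patch = LeafPatch(
                leaf_id=next_leaf_id,
                plant_id=plant_id,
                center=p + (lengths[k] / 2.0) * u,
                axis_u=u,
                axis_w=w,
                semi_len=lengths[k] / 2.0,
                semi_wid=widths[k] / 2.0,
                curvature=spec.curvature,
            )
            patches.append(patch)
            leaf_truths.append(
                LeafTruth(
                    leaf_id=next_leaf_id,
                    plant_id=plant_id,
                    length=float(lengths[k]),
                    width=float(widths[k]),
                    area_m2=patch.true_area_m2,
                )
            )
            next_leaf_id += 1

        head_radius = spec.head_radius
        if head_radius is not None:
            heads.append(
                HeadBall(
                    plant_id=plant_id,
                    center=np.array([p[0], p[1], spec.head_center_z]),
                    radius=head_radius,
                )
            )
        plants.append(
            PlantTruth(
                plant_id=plant_id,
                attachment=p,
                leaves=leaf_truths,
                head_radius=head_radius,
                head_volume=None if head_radius is None else sphere_volume(head_radius),
            )
        )

    scene = SceneGroundTruth(camera=camera, plants=plants, patches=patches, heads=heads)
    _render_true(scene)
    return scene


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _pixel_grids(camera: CameraModel, bbox: tuple[int, int, int, int]):
    c0, c1, r0, r1 = bbox
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    cx, cy = camera.principal_point
    u = (cols - cx) / camera.focal_length  # direction tangents
    v = (rows - cy) / camera.focal_length
    return np.meshgrid(u, v), (cols, rows)


def _project_bbox(points: np.ndarray, camera: CameraModel, margin: int = 2):
    d = camera.camera_height - points[:, 2]
    cx, cy = camera.principal_point
    col = cx + camera.focal_length * points[:, 0] / d
    row = cy + camera.focal_length * points[:, 1] / d
    w, h = camera.image_size
    c0 = max(0, int(np.floor(col.min())) - margin)
    c1 = min(w, int(np.ceil(col.max())) + margin + 1)
    r0 = max(0, int(np.floor(row.min())) - margin)
    r1 = min(h, int(np.ceil(row.max())) + margin + 1)
    return c0, c1, r0, r1


def _rasterize_patch(patch: LeafPatch, camera: CameraModel):
    """Per-pixel candidate depth of a planar elliptical patch.

    For pixel tangents (u, v), the ray meets the leaf plane z = a·x + b·y + c
    at axial depth d = (H_cam − c) / (1 + a·u + b·v); the hit is kept when its
    leaf-local elliptical coordinates fall inside the ellipse.
    """
    theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    boundary = (
        patch.center[None, :]
        + np.outer(patch.semi_len * np.cos(theta), patch.axis_u)
        + np.outer(patch.semi_wid * np.sin(theta), patch.axis_w)
    )
    bbox = _project_bbox(boundary, camera)
    if bbox[0] >= bbox[1] or bbox[2] >= bbox[3]:
        return None
    (U, V), _ = _pixel_grids(camera, bbox)
    a, b, c = patch.plane
    H = camera.camera_height
    denom = 1.0 + a * U + b * V
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (H - c) / denom
    x = U * d
    y = V * d
    z = H - d
    rel = np.stack([x - patch.center[0], y - patch.center[1], z - patch.center[2]], axis=-1)
    s = rel @ patch.axis_u
    t = rel @ patch.axis_w
    inside = (
        (d > 0)
        & np.isfinite(d)
        & ((s / patch.semi_len) ** 2 + (t / patch.semi_wid) ** 2 <= 1.0)
    )
    if patch.curvature > 0:
        # cylindrical bend: drop the true plane by curvature·t² and re-solve depth
        sag = patch.curvature * (t / patch.semi_wid) ** 2 * patch.semi_wid
        d = d + sag  # farther from the nadir camera by the sag
    return bbox, d, inside


def _rasterize_head(head: HeadBall, camera: CameraModel):
    """Per-pixel candidate depth of a sphere: nearest ray-sphere intersection."""
    H = camera.camera_height
    apex_d = H - (head.center[2] + head.radius)
    if apex_d <= 0:
        raise CabbageMorphError("head pokes above the camera")
    # conservative silhouette bound: the perspective silhouette is wider than
    # any projected surface point, so size the box at the apex depth
    d_center = H - head.center[2]
    d_near = d_center - head.radius
    cx_pp, cy_pp = camera.principal_point
    col_c = cx_pp + camera.focal_length * head.center[0] / d_near
    row_c = cy_pp + camera.focal_length * head.center[1] / d_near
    half = camera.focal_length * head.radius / d_near
    w_img, h_img = camera.image_size
    bbox = (
        max(0, int(np.floor(col_c - half)) - 3),
        min(w_img, int(np.ceil(col_c + half)) + 4),
        max(0, int(np.floor(row_c - half)) - 3),
        min(h_img, int(np.ceil(row_c + half)) + 4),
    )
    if bbox[0] >= bbox[1] or bbox[2] >= bbox[3]:
        return None
    (U, V), _ = _pixel_grids(camera, bbox)
    cx, cy, cz = head.center
    w0 = H - cz
    A = U**2 + V**2 + 1.0
    B = -2.0 * (U * cx + V * cy + w0)
    C = cx**2 + cy**2 + w0**2 - head.radius**2
    disc = B**2 - 4 * A * C
    inside = disc >= 0
    d = np.full(U.shape, np.inf)
    sq = np.sqrt(np.maximum(disc, 0.0))
    d_near = (-B - sq) / (2 * A)
    d[inside] = d_near[inside]
    inside &= d > 0
    return bbox, d, inside


def _render_true(scene: SceneGroundTruth) -> None:
    """Z-buffer render of the noise-free depth and instance label maps."""
    camera = scene.camera
    w, h = camera.image_size
    H = camera.camera_height
    depth = np.full((h, w), H, dtype=float)  # bare ground
    leaf_lab = np.zeros((h, w), dtype=np.int32)
    head_lab = np.zeros((h, w), dtype=np.int32)
    plant_lab = np.zeros((h, w), dtype=np.int32)
    # amodal head silhouette: what a human annotator outlines, leaves ignored
    head_amodal = np.zeros((h, w), dtype=np.int32)
    head_depth = np.full((h, w), np.inf)

    footprint: dict[int, int] = {}
    surfaces = []
    for patch in scene.patches:
        out = _rasterize_patch(patch, camera)
        if out is None:
            continue
        footprint[patch.leaf_id] = int(out[2].sum())
        surfaces.append(("leaf", patch, out))
    for head in scene.heads:
        out = _rasterize_head(head, camera)
        if out is not None:
            surfaces.append(("head", head, out))

    for kind, obj, (bbox, d, inside) in surfaces:
        c0, c1, r0, r1 = bbox
        sub = depth[r0:r1, c0:c1]
        win = inside & (d < sub)
        sub[win] = d[win]
        if kind == "leaf":
            leaf_lab[r0:r1, c0:c1][win] = obj.leaf_id
            head_lab[r0:r1, c0:c1][win] = 0
            plant_lab[r0:r1, c0:c1][win] = obj.plant_id
        else:
            head_lab[r0:r1, c0:c1][win] = obj.plant_id
            leaf_lab[r0:r1, c0:c1][win] = 0
            plant_lab[r0:r1, c0:c1][win] = obj.plant_id
            hwin = inside & (d < head_depth[r0:r1, c0:c1])
            head_depth[r0:r1, c0:c1][hwin] = d[hwin]
            head_amodal[r0:r1, c0:c1][hwin] = obj.plant_id

    scene.depth_true = depth
    scene.label_maps = {
        "leaf": leaf_lab,
        "head": head_lab,
        "plant": plant_lab,
        "head_amodal": head_amodal,
    }

    # per-leaf occlusion fraction: share of the leaf's own footprint lost to
    # nearer surfaces (or the image border)
    visible = {int(i): int(n) for i, n in zip(*np.unique(leaf_lab, return_counts=True)) if i > 0}
    for plant in scene.plants:
        for lf in plant.leaves:
            total = footprint.get(lf.leaf_id, 0)
            vis = visible.get(lf.leaf_id, 0)
            lf.occlusion = 1.0 - vis / total if total else 1.0


def render(
    scene: SceneGroundTruth,
    noise_sd: float = 0.0,
    outlier_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[DepthRaster, dict[str, np.ndarray]]:
    """Noisy observation of a scene: Gaussian depth noise plus a fraction of
    pixels replaced by uniform outliers in [0.3·H, H]. Deterministic per seed."""
    if scene.depth_true is None:
        _render_true(scene)
    rng = np.random.default_rng(seed)
    depth = scene.depth_true.copy()
    if noise_sd > 0:
        depth += rng.normal(0.0, noise_sd, size=depth.shape)
    if outlier_fraction > 0:
        H = scene.camera.camera_height
        hit = rng.random(depth.shape) < outlier_fraction
        depth[hit] = rng.uniform(0.3 * H, H, size=int(hit.sum()))
    np.clip(depth, 1.0, None, out=depth)
    return DepthRaster(values=depth, invalid_sentinel=0.0), dict(scene.label_maps)


# ---------------------------------------------------------------------------
# Head occlusion
# ---------------------------------------------------------------------------

def occlude_head(
    scene: SceneGroundTruth,
    cover_fraction: float,
    plant_id: int | None = None,
    seed: int = 0,
) -> SceneGroundTruth:
    """Return a copy of the scene with extra leaves draped over the head so
    that roughly ``cover_fraction`` of the head's image disc is hidden.

    Occluder leaves are horizontal elliptical patches floating just above the
    apex; they carry ``is_occluder=True`` in the truth so morphometry tests can
    exclude them. The truth keeps the true head radius; a cover fraction above
    0.95 flags low head visibility.
    """
    if not (0.0 <= cover_fraction < 1.0):
        raise CabbageMorphError("cover_fraction must lie in [0, 1)")
    scene = copy.deepcopy(scene)
    heads = [
        hb for hb in scene.heads if plant_id is None or hb.plant_id == plant_id
    ]
    if not heads:
        raise CabbageMorphError("scene has no head to occlude")
    rng = np.random.default_rng(seed)
    camera = scene.camera
    next_id = max((p.leaf_id for p in scene.patches), default=0) + 1

    for hb in heads:
        R = hb.radius
        apex_z = hb.center[2] + R
        z_occ = apex_z + 15.0
        d_occ = camera.camera_height - z_occ
        # exact projected head silhouette from the scene's amodal render
        disc = scene.label_maps["head_amodal"] == hb.plant_id
        disc_n = int(disc.sum())
        if disc_n == 0:
            continue
        covered = np.zeros_like(disc)

        plant = next(p for p in scene.plants if p.plant_id == hb.plant_id)
        attempts = 0
        # accept a candidate patch only while it keeps coverage near the
        # target; small patches (≈5 % of the disc each) give fine control
        while (
            cover_fraction > 0
            and covered[disc].sum() / disc_n < cover_fraction - 0.02
            and attempts < 500
        ):
            attempts += 1
            rho = R * np.sqrt(rng.random())
            ang = rng.uniform(0, 2 * np.pi)
            center = np.array(
                [hb.center[0] + rho * np.cos(ang), hb.center[1] + rho * np.sin(ang), z_occ]
            )
            phi = rng.uniform(0, 2 * np.pi)
            u = np.array([np.cos(phi), np.sin(phi), 0.0])
            wv = np.array([-np.sin(phi), np.cos(phi), 0.0])
            patch = LeafPatch(
                leaf_id=next_id,
                plant_id=hb.plant_id,
                center=center,
                axis_u=u,
                axis_w=wv,
                semi_len=0.32 * R,
                semi_wid=0.18 * R,
                is_occluder=True,
            )
            out = _rasterize_patch(patch, camera)
            if out is None:
                continue
            (c0, c1, r0, r1), _, inside = out
            trial = covered.copy()
            trial[r0:r1, c0:c1] |= inside
            if trial[disc].sum() / disc_n > cover_fraction + 0.03:
                continue  # would overshoot; try another position
            covered = trial
            scene.patches.append(patch)
            plant.leaves.append(
                LeafTruth(
                    leaf_id=next_id,
                    plant_id=hb.plant_id,
                    length=patch.true_length,
                    width=2 * patch.semi_wid,
                    area_m2=patch.true_area_m2,
                    is_occluder=True,
                )
            )
            next_id += 1
        if cover_fraction > 0.95:
            plant.low_head_visibility = True

    _render_true(scene)
    return scene
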